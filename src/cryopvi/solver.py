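"""Axisymmetric finite-volume integrator for the Pennes bioheat equation.

The temperature of perfused tissue obeys

    rho c dT/dt = div(k grad T) + Wb Cb (Ta - T) + Qm

with conduction through the labeled material regions, a blood-perfusion sink
pulling tissue toward arterial temperature Ta while the tissue is unfrozen,
and metabolic heat Qm (zero for the solid balloon, and not reported for the
tissues, so zero by default throughout).

Discretization: cell-centered finite volumes on the (r, z) grid with
harmonic-mean conductivity at material interfaces (exact steady flux across
discontinuities), symmetric at the axis, insulated far z-ends, and a fixed
(Dirichlet) exterior radial boundary at the outermost layer's initial
temperature.
The balloon region is pinned to the thermocouple-derived surface schedule
(Dirichlet mode, default) or replaced by a prescribed contact-surface flux
(Neumann mode).

Time integration is implicit in the stiff conduction operator (backward
Euler by default, Crank-Nicolson optional).  The perfusion sink is treated
explicitly with a lagged frozen-state mask: its rate constant Wb Cb / rho c
is about 0.01 s^-1, so at the timesteps of interest the explicit coupling is
benign, and it keeps the system matrix constant over a run (a single sparse
LU factorization).  Steady-state solves treat perfusion implicitly and
iterate the frozen mask to a fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .materials import (
    CELSIUS_OFFSET,
    ComputationalDomain,
    MaterialProperties,
    PerfusionParameters,
)

SCHEMES = ("implicit", "crank_nicolson")
BOUNDARY_MODES = ("dirichlet_schedule", "neumann_flux")


@dataclass
class SimulationConfig:
    """Numerical controls for the bioheat integration.

    ``frozen_cutoff_C`` is the local temperature below which the perfusion
    sink shuts off (blood flow ceases in frozen tissue); ``None`` keeps
    perfusion always on (used by closed-form verification).  The optional
    apparent-heat-capacity latent term spreads a phase-change enthalpy over
    ``mushy_window_C`` below 0 degC for sensitivity studies; it is off by
    default, matching the base model.
    """

    timestep: float = 0.1                  # s
    cell_size_mm: float = 0.15
    scheme: str = "implicit"
    boundary_mode: str = "dirichlet_schedule"
    latent_heat_enabled: bool = False
    latent_heat_J_per_kg: float = 250e3
    mushy_window_C: float = 2.0
    snapshot_interval: float = 10.0        # s
    perfusion_enabled: bool = True
    frozen_cutoff_C: Optional[float] = 0.0
    exterior_dirichlet: bool = True
    exterior_temperature_C: Optional[float] = None
    volumetric_source: Optional[np.ndarray] = None   # W m^-3 per cell

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.cell_size_mm <= 0:
            raise ValueError("cell_size_mm must be > 0")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ValueError(f"boundary_mode must be one of {BOUNDARY_MODES}")

    @property
    def theta(self) -> float:
        return 1.0 if self.scheme == "implicit" else 0.5


@dataclass
class TemperatureField:
    """Per-cell temperature (K) on a domain at one instant."""

    domain: ComputationalDomain
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.domain.nr, self.domain.nz):
            raise ValueError("field shape does not match domain")
        if not np.isfinite(self.values).all():
            raise ValueError("temperature field contains non-finite values")

    @property
    def celsius(self) -> np.ndarray:
        return self.values - CELSIUS_OFFSET

    def min_tissue_celsius(self) -> float:
        return float(self.celsius[self.domain.tissue_mask].min())


@dataclass
class TemperatureHistory:
    """Snapshots plus per-step diagnostics from a therapy run."""

    domain: ComputationalDomain
    snapshot_times: np.ndarray
    snapshots: list[np.ndarray]
    step_times: np.ndarray
    min_tissue_C: np.ndarray
    balloon_power_W: np.ndarray     # conductive heat rate balloon -> tissue
    boundary_power_W: np.ndarray    # scheme-consistent total boundary power
    source_power_W: np.ndarray      # perfusion + metabolic + extra sources
    enthalpy_J: np.ndarray          # active-region enthalpy after each step

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.snapshot_times) > 0):
            raise ValueError("snapshot times must be strictly increasing")

    def field_at(self, t: float) -> TemperatureField:
        """Snapshot nearest to time t."""
        i = int(np.argmin(np.abs(self.snapshot_times - t)))
        return TemperatureField(self.domain, self.snapshots[i].copy(),
                                time=float(self.snapshot_times[i]))

    @property
    def final_field(self) -> TemperatureField:
        return TemperatureField(self.domain, self.snapshots[-1].copy(),
                                time=float(self.snapshot_times[-1]))


def perfusion_mass_rate(volumetric_perfusion: float, blood_density: float) -> float:
    """Mass perfusion rate Wb (kg m^-3 s^-1) from the volumetric rate.

    The volumetric rate in mL s^-1 cm^-3 is numerically s^-1 (mL/cm^3 = 1),
    so Wb is simply the product with blood density.
    """
    if volumetric_perfusion < 0 or blood_density < 0:
        raise ValueError("perfusion inputs must be >= 0")
    return volumetric_perfusion * blood_density


def analytic_1d_pennes(x: float | np.ndarray, surface_temp: float,
                       material: MaterialProperties,
                       perfusion: PerfusionParameters) -> float | np.ndarray:
    """Steady semi-infinite 1-D Pennes solution (degC), Qm = 0.

    T(x) = Ta + (Ts - Ta) exp(-x / delta), delta = sqrt(k / (Wb Cb)).
    Serves as the closed-form oracle for solver verification.
    """
    wbcb = perfusion.sink_coefficient
    if wbcb <= 0:
        raise ValueError("Wb * Cb must be > 0 for the perfused closed form")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    delta = math.sqrt(material.thermal_conductivity / wbcb)
    ta = perfusion.arterial_temperature - CELSIUS_OFFSET
    out = ta + (surface_temp - ta) * np.exp(-x / delta)
    return float(out) if out.ndim == 0 else out


class PennesSolver:
    """Assembled operators for one domain + config; reused across steps."""

    def __init__(self, domain: ComputationalDomain, config: SimulationConfig):
        self.domain = domain
        self.config = config
        nr, nz = domain.nr, domain.nz
        self.n = nr * nz
        self.shape = (nr, nz)
        idx = np.arange(self.n).reshape(nr, nz)

        self.pinned = domain.balloon_mask.ravel()
        active = ~self.pinned

        k = domain.property_field("thermal_conductivity")
        self.heat_capacity = (domain.property_field("density")
                              * domain.property_field("specific_heat")
                              * domain.cell_volumes())          # J/K per cell
        self.volumes = domain.cell_volumes()

        # Perfusion sink coefficient (W/K per cell) and arterial temperature.
        perf = domain.perfusion_field("volumetric_perfusion") \
            * domain.perfusion_field("blood_density") \
            * domain.perfusion_field("blood_specific_heat")
        if not config.perfusion_enabled:
            perf = np.zeros_like(perf)
        self.perf_WK = (perf * self.volumes).ravel()
        self.perf_WK[self.pinned] = 0.0
        self.ta_K = domain.perfusion_field("arterial_temperature").ravel()
        self.qm_W = (domain.perfusion_field("metabolic_heat")
                     * self.volumes).ravel()
        self.qm_W[self.pinned] = 0.0
        if config.volumetric_source is not None:
            src = np.asarray(config.volumetric_source, dtype=float)
            if src.shape != self.shape:
                raise ValueError("volumetric_source shape must match the grid")
            self.src_W = (src * self.volumes).ravel()
            self.src_W[self.pinned] = 0.0
        else:
            self.src_W = np.zeros(self.n)

        # Face lists: endpoints, harmonic conductance, area, half-spacing.
        a_r = domain.radial_face_areas()
        a_z = domain.axial_face_areas()
        kh_r = 2.0 * k[:-1, :] * k[1:, :] / (k[:-1, :] + k[1:, :])
        kh_z = 2.0 * k[:, :-1] * k[:, 1:] / (k[:, :-1] + k[:, 1:])
        area_r = np.broadcast_to(a_r[1:nr, None], (nr - 1, nz))
        area_z = np.broadcast_to(a_z[:, None], (nr, nz - 1))

        faces_p = np.concatenate([idx[:-1, :].ravel(), idx[:, :-1].ravel()])
        faces_q = np.concatenate([idx[1:, :].ravel(), idx[:, 1:].ravel()])
        faces_g = np.concatenate([(kh_r * area_r / domain.dr).ravel(),
                                  (kh_z * area_z / domain.dz).ravel()])
        faces_area = np.concatenate([area_r.ravel(), area_z.ravel()])
        faces_halfd = np.concatenate([
            np.full((nr - 1) * nz, domain.dr / 2.0),
            np.full(nr * (nz - 1), domain.dz / 2.0)])

        p_pin = self.pinned[faces_p]
        q_pin = self.pinned[faces_q]
        one_pin = p_pin ^ q_pin
        act_side = np.where(p_pin, faces_q, faces_p)[one_pin]
        self.b_const = np.zeros(self.n)
        k_flat = k.ravel()

        if config.boundary_mode == "neumann_flux":
            # Decouple the balloon; prescribe flux on its contact surface.
            flux = (domain.balloon.surface_flux_magnitude
                    if domain.balloon is not None else 0.0)
            self.b_const[act_side] += flux * faces_area[one_pin]
            self._neumann_power = float(np.sum(flux * faces_area[one_pin]))
            self.bdir_act = np.empty(0, dtype=int)
            self.bdir_g = np.empty(0)
        else:
            # The schedule prescribes the balloon *surface* temperature, so
            # the Dirichlet value sits on the balloon-adjacent faces: the
            # active cell couples to it through its own half-cell only
            # (no spurious polyurethane resistance).
            self._neumann_power = 0.0
            self.bdir_act = act_side
            self.bdir_g = (k_flat[act_side] * faces_area[one_pin]
                           / faces_halfd[one_pin])

        # Interior faces between two active cells.
        keep = ~(p_pin | q_pin)
        faces_p, faces_q, faces_g = faces_p[keep], faces_q[keep], faces_g[keep]

        # Diffusion operator L (W/K): rows for active cells only.
        rows, cols, vals = [], [], []
        for a, b in ((faces_p, faces_q), (faces_q, faces_p)):
            rows.append(a); cols.append(a); vals.append(-faces_g)
            rows.append(a); cols.append(b); vals.append(faces_g)
        if self.bdir_act.size:
            rows.append(self.bdir_act); cols.append(self.bdir_act)
            vals.append(-self.bdir_g)

        # Exterior radial Dirichlet boundary at the outer face.
        if config.exterior_dirichlet:
            outer = idx[nr - 1, :]
            g_ext = k[nr - 1, :] * a_r[nr] / (domain.dr / 2.0)
            if config.exterior_temperature_C is None:
                t_ext = domain.initial_temperatures()[nr - 1, :]
            else:
                t_ext = np.full(nz, config.exterior_temperature_C + CELSIUS_OFFSET)
            m = ~self.pinned[outer]
            rows.append(outer[m]); cols.append(outer[m]); vals.append(-g_ext[m])
            self.b_const[outer[m]] += (g_ext * t_ext)[m]
            self.ext_idx, self.ext_g, self.ext_T = outer[m], g_ext[m], t_ext[m]
        else:
            self.ext_idx = np.empty(0, dtype=int)
            self.ext_g = np.empty(0)
            self.ext_T = np.empty(0)

        self.L = coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n)).tocsr()
        self._lu_cache: dict = {}

    # -- physics terms ----------------------------------------------------
    def _perf_active(self, t_flat: np.ndarray) -> np.ndarray:
        """Perfusion coefficient (W/K) with the frozen cutoff applied.

        The cutoff models capillary flow ceasing in frozen tissue, so it
        applies to the tissue regions only; the lumen-blood sink is the
        stand-in for advection by flowing blood and stays on regardless of
        the local temperature.
        """
        cut = self.config.frozen_cutoff_C
        if cut is None:
            return self.perf_WK
        frozen_tissue = (t_flat - CELSIUS_OFFSET <= cut) \
            & self.domain.tissue_mask.ravel()
        return np.where(frozen_tissue, 0.0, self.perf_WK)

    def _capacity(self, t_flat: np.ndarray) -> np.ndarray:
        """Effective heat capacity (J/K), with optional apparent latent term."""
        c = self.heat_capacity.ravel()
        if not self.config.latent_heat_enabled:
            return c
        tc = t_flat - CELSIUS_OFFSET
        w = self.config.mushy_window_C
        mushy = (tc > -w) & (tc <= 0.0) & self.domain.tissue_mask.ravel()
        rho = self.domain.property_field("density").ravel()
        extra = rho * self.config.latent_heat_J_per_kg / w * self.volumes.ravel()
        return np.where(mushy, c + extra, c)

    def _bc_kelvin(self, t_flat: np.ndarray,
                   boundary_value_C: Optional[float]) -> float:
        if boundary_value_C is not None:
            return boundary_value_C + CELSIUS_OFFSET
        if self.pinned.any():
            return float(t_flat[self.pinned].mean())
        return 0.0

    def rhs_rate(self, field: TemperatureField,
                 boundary_value_C: Optional[float] = None) -> np.ndarray:
        """Instantaneous dT/dt (K/s) of the semi-discrete Pennes system.

        ``boundary_value_C`` is the balloon surface temperature; by default
        the pinned balloon-region value of the field itself is used.
        """
        t = field.values.ravel()
        power = self.L @ t + self.b_const + self.qm_W + self.src_W \
            + self._perf_active(t) * (self.ta_K - t)
        if self.bdir_act.size:
            np.add.at(power, self.bdir_act,
                      self.bdir_g * self._bc_kelvin(t, boundary_value_C))
        rate = power / self.heat_capacity.ravel()
        rate[self.pinned] = 0.0
        return rate.reshape(self.shape)

    def boundary_power(self, t_flat: np.ndarray,
                       boundary_value_C: Optional[float] = None
                       ) -> tuple[float, float]:
        """(balloon, exterior) conductive heat rate into the active region, W."""
        if self.config.boundary_mode == "neumann_flux":
            qb = self._neumann_power
        else:
            bc = self._bc_kelvin(t_flat, boundary_value_C)
            qb = float(np.sum(self.bdir_g * (bc - t_flat[self.bdir_act])))
        qe = float(np.sum(self.ext_g * (self.ext_T - t_flat[self.ext_idx])))
        return qb, qe

    def enthalpy(self, t_flat: np.ndarray) -> float:
        """Sensible enthalpy of the active (non-pinned) region, J."""
        c = self.heat_capacity.ravel()
        return float(np.sum(c[~self.pinned] * t_flat[~self.pinned]))

    # -- time stepping ----------------------------------------------------
    def _lu(self, dt: float, capacity: np.ndarray):
        key = (dt, self.config.theta,
                None if not self.config.latent_heat_enabled
                else capacity.tobytes())
        lu = self._lu_cache.get(key)
        if lu is None:
            diag = np.where(self.pinned, 1.0, capacity / dt)
            a = (coo_matrix((diag, (np.arange(self.n), np.arange(self.n))),
                            shape=(self.n, self.n))
                 - self.config.theta * self.L)
            lu = splu(csc_matrix(a))
            self._lu_cache.clear()      # one entry is enough in practice
            self._lu_cache[key] = lu
        return lu

    def step(self, field: TemperatureField, dt: float,
             boundary_value_C: float,
             boundary_value_old_C: Optional[float] = None
             ) -> tuple[TemperatureField, dict]:
        """Advance one timestep; returns the new field plus diagnostics.

        ``boundary_value_C`` is the balloon surface temperature at the new
        time level; for Crank-Nicolson the old-time value may be supplied
        (defaults to the new one).
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        theta = self.config.theta
        bc_old_C = (boundary_value_C if boundary_value_old_C is None
                    else boundary_value_old_C)
        t_old = field.values.ravel()
        cap = self._capacity(t_old)
        lu = self._lu(dt, cap)

        perf = self._perf_active(t_old)
        source = self.qm_W + self.src_W + perf * (self.ta_K - t_old)
        rhs = cap / dt * t_old + (1.0 - theta) * (self.L @ t_old) \
            + self.b_const + source
        if self.bdir_act.size:
            bc_mix = (theta * (boundary_value_C + CELSIUS_OFFSET)
                      + (1.0 - theta) * (bc_old_C + CELSIUS_OFFSET))
            np.add.at(rhs, self.bdir_act, self.bdir_g * bc_mix)
        rhs[self.pinned] = boundary_value_C + CELSIUS_OFFSET \
            if self.config.boundary_mode == "dirichlet_schedule" \
            else t_old[self.pinned]
        t_new = lu.solve(rhs)
        if not np.isfinite(t_new).all():
            raise RuntimeError(
                "linear solve produced non-finite temperatures "
                f"(dt={dt}, scheme={self.config.scheme})")

        qb_new, qe_new = self.boundary_power(t_new, boundary_value_C)
        qb_old, qe_old = self.boundary_power(t_old, bc_old_C)
        diag = {
            "balloon_power_W": qb_new,
            "boundary_power_W": theta * (qb_new + qe_new)
            + (1.0 - theta) * (qb_old + qe_old),
            "source_power_W": float(np.sum(source[~self.pinned])),
            "enthalpy_J": self.enthalpy(t_new),
        }
        new = TemperatureField(self.domain, t_new.reshape(self.shape),
                               time=field.time + dt)
        return new, diag

    # -- steady state -----------------------------------------------------
    def solve_steady(self, boundary_value_C: float,
                     initial_guess: Optional[np.ndarray] = None,
                     max_mask_iter: int = 50) -> TemperatureField:
        """Steady solution with implicit perfusion; frozen-mask fixed point."""
        t = (initial_guess.ravel().copy() if initial_guess is not None
             else self.domain.initial_temperatures().ravel().copy())
        bc = boundary_value_C + CELSIUS_OFFSET
        for _ in range(max_mask_iter):
            perf = self._perf_active(t)
            diag_extra = np.where(self.pinned, 1.0, perf)
            a = (coo_matrix((diag_extra,
                             (np.arange(self.n), np.arange(self.n))),
                            shape=(self.n, self.n)) - self.L)
            rhs = self.b_const + self.qm_W + self.src_W + perf * self.ta_K
            if self.bdir_act.size:
                np.add.at(rhs, self.bdir_act, self.bdir_g * bc)
            rhs[self.pinned] = bc
            t_new = splu(csc_matrix(a)).solve(rhs)
            if np.array_equal(self._perf_active(t_new) > 0, perf > 0):
                t = t_new
                break
            t = t_new
        return TemperatureField(self.domain, t.reshape(self.shape))


# -- module-level operation surface --------------------------------------

def pennes_rhs(field: TemperatureField, domain: ComputationalDomain,
               config: SimulationConfig | None = None) -> np.ndarray:
    """Per-cell dT/dt (K/s) of the discretized Pennes equation."""
    if field.domain is not domain and field.values.shape != (domain.nr, domain.nz):
        raise ValueError("field does not match domain")
    return PennesSolver(domain, config or SimulationConfig()).rhs_rate(field)


def step(field: TemperatureField, dt: float, boundary_value_C: float,
         config: SimulationConfig) -> TemperatureField:
    """Single implicit (or Crank-Nicolson) update of the field."""
    solver = PennesSolver(field.domain, config)
    new, _ = solver.step(field, dt, boundary_value_C)
    return new


def boundary_heat_rate(field: TemperatureField,
                       domain: ComputationalDomain) -> float:
    """Conductive heat rate (W) across the balloon contact surface.

    Sign convention: heat delivered by the balloon to its surroundings, so
    the value is negative whenever the balloon is colder than the adjacent
    tissue (the cryocatheter acts as a heat absorber).
    """
    solver = PennesSolver(domain, SimulationConfig(
        boundary_mode="dirichlet_schedule"))
    qb, _ = solver.boundary_power(field.values.ravel())
    return qb


def initial_field(domain: ComputationalDomain, config: SimulationConfig,
                  schedule_start_C: Optional[float] = None) -> TemperatureField:
    """Material-library initial temperatures; in Dirichlet mode the balloon
    starts at the schedule value (the thermocouple reads body temperature at
    insertion, not the cold-state polyurethane default)."""
    t0 = domain.initial_temperatures().copy()
    if (config.boundary_mode == "dirichlet_schedule"
            and schedule_start_C is not None):
        t0[domain.balloon_mask] = schedule_start_C + CELSIUS_OFFSET
    return TemperatureField(domain, t0, time=0.0)


def run_therapy(domain: ComputationalDomain, schedule,
                config: SimulationConfig) -> TemperatureHistory:
    """Integrate the full (two-cycle) therapy schedule; deterministic.

    Snapshots are stored every ``config.snapshot_interval`` seconds plus the
    initial and final instants; per-step diagnostics are stored for every
    step.
    """
    solver = PennesSolver(domain, config)
    dt = config.timestep
    n_steps = int(round(schedule.duration / dt))
    if abs(n_steps * dt - schedule.duration) > 1e-9 * schedule.duration:
        raise ValueError("timestep must divide the schedule duration")
    every = max(1, int(round(config.snapshot_interval / dt)))

    fld = initial_field(domain, config, schedule_start_C=float(schedule(0.0)))
    snap_t = [0.0]
    snaps = [fld.values.copy()]
    st = np.empty(n_steps)
    min_c = np.empty(n_steps)
    qb = np.empty(n_steps)
    qtot = np.empty(n_steps)
    qsrc = np.empty(n_steps)
    enth = np.empty(n_steps)

    for n in range(n_steps):
        t_new = (n + 1) * dt
        fld, d = solver.step(
            fld, dt, float(schedule(min(t_new, schedule.duration))),
            boundary_value_old_C=float(schedule(n * dt)))
        st[n] = t_new
        min_c[n] = fld.min_tissue_celsius()
        qb[n] = d["balloon_power_W"]
        qtot[n] = d["boundary_power_W"]
        qsrc[n] = d["source_power_W"]
        enth[n] = d["enthalpy_J"]
        if (n + 1) % every == 0 or n == n_steps - 1:
            snap_t.append(t_new)
            snaps.append(fld.values.copy())

    return TemperatureHistory(
        domain=domain, snapshot_times=np.asarray(snap_t), snapshots=snaps,
        step_times=st, min_tissue_C=min_c, balloon_power_W=qb,
        boundary_power_W=qtot, source_power_W=qsrc, enthalpy_J=enth)
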