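"""Independent verification harnesses for the bioheat solver.

These build small purpose-made domains and compare the solver against
closed-form or manufactured solutions; they are deliberately separate from
the implementation paths they check.
"""

import numpy as np

from cryopvi.materials import (
    LABEL_BALLOON,
    LABEL_WALL,
    make_slab_domain,
)
from cryopvi.solver import PennesSolver, SimulationConfig, analytic_1d_pennes


def quasi_1d_oracle_error(cell_mm: float = 0.1, length_mm: float = 40.0,
                          surface_temp_C: float = 0.0) -> float:
    """L-infinity relative error of the steady solver vs the closed form.

    Planar slab of vascular-wall material with the surface temperature
    prescribed on the face behind the first cell column and the far side
    held at arterial temperature; perfusion always on, matching the
    semi-infinite exponential solution (the far boundary sits ~8 decay
    lengths out, so its influence is negligible at the 1% level).
    """
    nr = int(round(length_mm / cell_mm)) + 1
    labels = np.full((nr, 4), LABEL_WALL, dtype=np.int8)
    labels[0, :] = LABEL_BALLOON
    dom = make_slab_domain(nr, 4, cell_mm, labels=labels, axisymmetric=False)
    mat = dom.materials["vascular_wall"]
    perf = dom.perfusion["vascular_wall"]
    ta_C = perf.arterial_temperature - 273.15
    cfg = SimulationConfig(frozen_cutoff_C=None, exterior_dirichlet=True,
                           exterior_temperature_C=ta_C)
    solver = PennesSolver(dom, cfg)
    fld = solver.solve_steady(surface_temp_C)
    # Dirichlet surface sits on the face of the first active cell.
    x = (np.arange(1, nr) - 0.5) * cell_mm * 1e-3
    exact = analytic_1d_pennes(x, surface_temp_C, mat, perf)
    return float(np.abs(fld.celsius[1:, 1] - exact).max()
                 / abs(surface_temp_C - ta_C))


def _mms_error(cell_mm: float, radius_mm: float = 8.0,
               height_mm: float = 16.0) -> float:
    """L2 error against a manufactured axisymmetric steady solution.

    T = Ta + 20 cos(a r) cos(b z) with a = pi/(2R), b = pi/H satisfies the
    symmetry, insulated-end and exterior-Dirichlet boundary conditions; the
    matching volumetric source is supplied analytically.
    """
    nr = int(round(radius_mm / cell_mm))
    nz = int(round(height_mm / cell_mm))
    dom = make_slab_domain(nr, nz, cell_mm, labels=LABEL_WALL,
                           axisymmetric=True)
    mat = dom.materials["vascular_wall"]
    perf = dom.perfusion["vascular_wall"]
    k = mat.thermal_conductivity
    wbcb = perf.sink_coefficient
    ta = perf.arterial_temperature
    a = np.pi / 2.0 / (radius_mm * 1e-3)
    b = np.pi / (height_mm * 1e-3)
    r = dom.r_centers[:, None]
    z = dom.z_centers[None, :]
    amp = 20.0
    t_exact = ta + amp * np.cos(a * r) * np.cos(b * z)
    source = (k * amp * np.cos(b * z) * (a * np.sin(a * r) / r
                                         + a ** 2 * np.cos(a * r))
              + k * b ** 2 * amp * np.cos(a * r) * np.cos(b * z)
              + wbcb * amp * np.cos(a * r) * np.cos(b * z))
    cfg = SimulationConfig(frozen_cutoff_C=None, exterior_dirichlet=True,
                           exterior_temperature_C=ta - 273.15,
                           volumetric_source=source)
    fld = PennesSolver(dom, cfg).solve_steady(0.0)
    err = fld.values - t_exact
    return float(np.sqrt(np.mean(err ** 2)))


def mms_convergence_order(h_coarse: float = 0.4) -> float:
    """Observed spatial order from one grid halving of the manufactured case."""
    e1 = _mms_error(h_coarse)
    e2 = _mms_error(h_coarse / 2.0)
    return float(np.log2(e1 / e2))


def conservation_error(n_steps: int = 200, dt: float = 0.1,
                       cell_mm: float = 0.5) -> float:
    """Relative enthalpy-balance defect with perfusion and metabolism off.

    Integrates a freezing transient on a small PV domain and compares the
    active-region enthalpy change with the time-integrated boundary heat
    rate; implicit finite volumes should balance to round-off.
    """
    from cryopvi.materials import build_domain, pv_parameters
    from cryopvi.protocol import build_schedule
    from cryopvi.solver import initial_field

    dom = build_domain(pv_parameters("right inferior"), resolution=cell_mm)
    cfg = SimulationConfig(timestep=dt, cell_size_mm=cell_mm,
                           perfusion_enabled=False)
    solver = PennesSolver(dom, cfg)
    from cryopvi.protocol import TherapyLog
    sched = build_schedule(TherapyLog("x", 10, 23, 32, -60.0), 30.0)
    fld = initial_field(dom, cfg, schedule_start_C=float(sched(0.0)))
    h0 = solver.enthalpy(fld.values.ravel())
    q_int = 0.0
    for n in range(n_steps):
        bc_new = float(sched((n + 1) * dt))
        fld, diag = solver.step(fld, dt, bc_new,
                                boundary_value_old_C=float(sched(n * dt)))
        q_int += dt * (diag["boundary_power_W"] + diag["source_power_W"])
    dh = solver.enthalpy(fld.values.ravel()) - h0
    return abs(dh - q_int) / abs(dh)
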