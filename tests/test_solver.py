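import numpy as np
import pytest

from cryopvi.materials import (
    LABEL_BALLOON,
    LABEL_WALL,
    MaterialProperties,
    PerfusionParameters,
    build_domain,
    default_materials,
    default_perfusion,
    make_slab_domain,
    pv_parameters,
)
from cryopvi.protocol import TherapyLog, build_schedule
from cryopvi.solver import (
    PennesSolver,
    SimulationConfig,
    TemperatureField,
    analytic_1d_pennes,
    boundary_heat_rate,
    initial_field,
    pennes_rhs,
    perfusion_mass_rate,
    run_therapy,
    step,
)
from verification import quasi_1d_oracle_error


def test_perfusion_mass_rate_unit_conversion():
    assert perfusion_mass_rate(0.012, 1057.0) == pytest.approx(12.684)
    assert perfusion_mass_rate(0.012, 1000.0) == pytest.approx(12.0)
    assert perfusion_mass_rate(0.0, 1057.0) == 0.0
    with pytest.raises(ValueError):
        perfusion_mass_rate(-0.01, 1000.0)


def _uniform_wall_slab(nr=5, nz=3, cell=1.0, k=None):
    mats = default_materials()
    if k is not None:
        mats = {**mats, "vascular_wall": MaterialProperties(
            "vascular_wall", k, 3600.0, 1200.0, 310.0)}
    return make_slab_domain(nr, nz, cell, labels=LABEL_WALL,
                            materials=mats, axisymmetric=False)


def test_rhs_zero_at_arterial_equilibrium():
    dom = _uniform_wall_slab()
    ta = dom.perfusion["vascular_wall"].arterial_temperature
    cfg = SimulationConfig(exterior_temperature_C=ta - 273.15,
                           frozen_cutoff_C=None)
    fld = TemperatureField(dom, np.full((5, 3), ta))
    assert np.abs(pennes_rhs(fld, dom, cfg)).max() < 1e-12


def test_rhs_perfusion_cools_toward_arterial():
    dom = _uniform_wall_slab(nr=1, nz=1)
    ta = dom.perfusion["vascular_wall"].arterial_temperature
    cfg = SimulationConfig(exterior_dirichlet=False, frozen_cutoff_C=None)
    fld = TemperatureField(dom, np.full((1, 1), ta + 5.0))
    rate = pennes_rhs(fld, dom, cfg)
    assert rate[0, 0] < 0
    expected = dom.perfusion["vascular_wall"].sink_coefficient * (-5.0) \
        / dom.materials["vascular_wall"].volumetric_heat_capacity
    assert rate[0, 0] == pytest.approx(expected)


def test_rhs_matches_hand_stencil():
    """Three-cell 1-D stencil, k=1, 1 mm spacing, T=(0,1,0) degC."""
    dom = _uniform_wall_slab(nr=3, nz=1, cell=1.0, k=1.0)
    cfg = SimulationConfig(exterior_dirichlet=False, perfusion_enabled=False)
    t = np.array([[0.0], [1.0], [0.0]]) + 273.15
    rate = pennes_rhs(TemperatureField(dom, t), dom, cfg)
    rho_c = 1200.0 * 3600.0
    assert rate[1, 0] == pytest.approx(1.0 * (0 + 0 - 2.0) / (rho_c * 1e-6))
    assert rate[0, 0] == pytest.approx(1.0 * 1.0 / (rho_c * 1e-6))


def test_analytic_1d_pennes_limits():
    mat = default_materials()["vascular_wall"]
    perf = default_perfusion()["vascular_wall"]
    assert analytic_1d_pennes(0.0, -30.0, mat, perf) == pytest.approx(-30.0)
    far = analytic_1d_pennes(0.5, -30.0, mat, perf)
    assert far == pytest.approx(perf.arterial_temperature - 273.15, abs=1e-6)
    # decay length sqrt(k / (Wb Cb)) = sqrt(1.3 / 50736) ~ 5.06 mm
    delta = np.sqrt(1.3 / (12.684 * 4000.0))
    assert delta == pytest.approx(5.06e-3, abs=1e-5)
    ta = perf.arterial_temperature - 273.15
    val = analytic_1d_pennes(delta, 0.0, mat, perf)
    assert (val - ta) / (0.0 - ta) == pytest.approx(np.exp(-1))
    with pytest.raises(ValueError):
        analytic_1d_pennes(0.1, 0.0, mat,
                           PerfusionParameters(volumetric_perfusion=0.0))


def test_steady_solver_matches_1d_oracle_and_improves_with_refinement():
    coarse = quasi_1d_oracle_error(cell_mm=0.4)
    fine = quasi_1d_oracle_error(cell_mm=0.1)
    assert fine < 0.01
    assert fine < coarse


def test_step_preserves_body_temperature_equilibrium():
    """Uniform field at the schedule temperature stays put."""
    perf = {k: PerfusionParameters(arterial_temperature=36.7 + 273.15)
            if k != "polyurethane" else PerfusionParameters(0.0)
            for k in default_perfusion()}
    dom = build_domain(pv_parameters("right inferior"), resolution=0.5,
                       perfusion=perf)
    cfg = SimulationConfig(timestep=0.5, exterior_temperature_C=36.7)
    fld = TemperatureField(dom, np.full((dom.nr, dom.nz), 36.7 + 273.15))
    out = step(fld, 0.5, 36.7, cfg)
    assert np.abs(out.values - fld.values).max() < 1e-9


def test_freeze_step_monotone_minimum():
    dom = build_domain(pv_parameters("right inferior"), resolution=0.5)
    cfg = SimulationConfig(timestep=0.5)
    solver = PennesSolver(dom, cfg)
    fld = initial_field(dom, cfg, schedule_start_C=36.7)
    last = fld.min_tissue_celsius()
    for bc in (-10.0, -30.0, -50.0, -60.0, -60.0, -60.0):
        fld, _ = solver.step(fld, 0.5, bc)
    assert fld.min_tissue_celsius() < last


def test_implicit_large_timestep_reaches_same_steady_state():
    """Backward Euler is unconditionally stable; dt only changes the path."""
    dom = build_domain(pv_parameters("right inferior"), resolution=0.5)
    results = []
    for dt in (0.5, 1.0):
        cfg = SimulationConfig(timestep=dt, perfusion_enabled=False)
        solver = PennesSolver(dom, cfg)
        fld = initial_field(dom, cfg, schedule_start_C=-40.0)
        for _ in range(int(600 / dt)):
            fld, _ = solver.step(fld, dt, -40.0)
        results.append(fld.values)
    assert np.abs(results[0] - results[1]).max() < 0.05


def test_crank_nicolson_stable_and_consistent():
    dom = build_domain(pv_parameters("right inferior"), resolution=0.5)
    log = TherapyLog("x", 10, 23, 32, -60.0, cycles=1)
    sched = build_schedule(log, 30.0)
    out = {}
    for scheme in ("implicit", "crank_nicolson"):
        cfg = SimulationConfig(timestep=0.5, scheme=scheme,
                               snapshot_interval=30.0)
        out[scheme] = run_therapy(dom, sched, cfg).final_field.values
    assert np.isfinite(out["crank_nicolson"]).all()
    assert np.abs(out["implicit"] - out["crank_nicolson"]).max() < 1.0


def test_boundary_heat_rate_sign_and_fourier_value():
    # uniform field -> zero flux
    dom = build_domain(pv_parameters("right inferior"), resolution=0.5)
    uniform = TemperatureField(dom, np.full((dom.nr, dom.nz), 300.0))
    assert boundary_heat_rate(uniform, dom) == pytest.approx(0.0, abs=1e-9)

    # steady planar slab: flux equals k A dT / L
    nr, nz, cell = 41, 2, 0.5
    labels = np.full((nr, nz), LABEL_WALL, dtype=np.int8)
    labels[0, :] = LABEL_BALLOON
    slab = make_slab_domain(nr, nz, cell, labels=labels, axisymmetric=False)
    ts, ta = -20.0, 37.0
    cfg = SimulationConfig(perfusion_enabled=False, exterior_dirichlet=True,
                           exterior_temperature_C=ta)
    fld = PennesSolver(slab, cfg).solve_steady(ts)
    q = PennesSolver(slab, cfg).boundary_power(fld.values.ravel(), ts)[0]
    k, area = 1.3, nz * cell * 1e-3
    length = (nr - 1) * cell * 1e-3       # Dirichlet face to Dirichlet face
    assert q == pytest.approx(k * area * (ts - ta) / length, rel=1e-6)
    assert q < 0     # balloon colder than tissue: heat absorbed


def test_neumann_flux_mode_extracts_heat():
    dom = build_domain(pv_parameters("right inferior"), resolution=0.5)
    cfg = SimulationConfig(timestep=0.5, boundary_mode="neumann_flux")
    solver = PennesSolver(dom, cfg)
    fld = TemperatureField(dom, dom.initial_temperatures())
    t0 = fld.min_tissue_celsius()
    for _ in range(20):
        fld, diag = solver.step(fld, 0.5, 0.0)
    assert fld.min_tissue_celsius() < t0
    assert diag["balloon_power_W"] < 0


def test_latent_heat_option_slows_front():
    dom = build_domain(pv_parameters("right inferior"), resolution=0.5)
    log = TherapyLog("x", 10, 23, 32, -60.0, cycles=1)
    sched = build_schedule(log, 30.0)
    base = SimulationConfig(timestep=0.5, snapshot_interval=30.0)
    apparent = SimulationConfig(timestep=0.5, snapshot_interval=30.0,
                                latent_heat_enabled=True)
    cold_base = run_therapy(dom, sched, base).min_tissue_C.min()
    cold_lat = run_therapy(dom, sched, apparent).min_tissue_C.min()
    assert cold_lat >= cold_base - 1e-9


def test_run_therapy_deterministic(coarse_config, packaged_logs):
    dom = coarse_config.build_domain()
    sched = build_schedule(packaged_logs[1], coarse_config.rewarm_duration_s)
    cfg = coarse_config.solver_config()
    h1 = run_therapy(dom, sched, cfg)
    h2 = run_therapy(dom, sched, cfg)
    assert all(np.array_equal(a, b)
               for a, b in zip(h1.snapshots, h2.snapshots))
    assert np.array_equal(h1.min_tissue_C, h2.min_tissue_C)
    assert np.array_equal(h1.balloon_power_W, h2.balloon_power_W)


def test_history_diagnostics_shape(coarse_run):
    _, schedule, history = coarse_run
    n_steps = int(round(schedule.duration / 0.5))
    for arr in (history.min_tissue_C, history.balloon_power_W,
                history.boundary_power_W, history.enthalpy_J):
        assert arr.shape == (n_steps,)
    assert np.all(np.diff(history.snapshot_times) > 0)
    assert history.final_field.time == schedule.duration
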