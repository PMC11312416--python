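import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryopvi.lesion import (
    CryoinjuryZone,
    analyze_history,
    classify_zone,
    extract_front,
    kelvin_to_celsius,
    lesion_area,
    lesion_depth,
    printed_lesion_area,
    summarize,
    summarize_therapies,
)
from cryopvi.materials import build_domain, pv_parameters
from cryopvi.solver import TemperatureField

TABLE_DEPTHS = [4.28, 3.24, 3.00, 3.96, 3.08]
TABLE_AREAS = [77.28, 58.50, 54.17, 71.50, 55.61]
TABLE_TM = [32.0, 33.0, 42.0, 34.0, 35.0]


def test_kelvin_to_celsius():
    assert kelvin_to_celsius(273.15) == 0.0
    assert kelvin_to_celsius(310.15) == pytest.approx(37.0)
    assert kelvin_to_celsius(198.15) == pytest.approx(-75.0)
    with pytest.raises(ValueError):
        kelvin_to_celsius(-1.0)


@pytest.mark.parametrize("t,zone", [
    (5.0, CryoinjuryZone.ABOVE_FREEZING),
    (0.0, CryoinjuryZone.MEMBRANE_RESISTANT),
    (-10.0, CryoinjuryZone.MEMBRANE_RESISTANT),
    (-15.0, CryoinjuryZone.EXTRACELLULAR_ICE),
    (-18.0, CryoinjuryZone.EXTRACELLULAR_ICE),
    (-20.0, CryoinjuryZone.INTRACELLULAR_ICE),
    (-30.0, CryoinjuryZone.VASOCONSTRICTION_MARKER),
    (-40.0, CryoinjuryZone.HOMOGENEOUS_NUCLEATION),
    (-45.0, CryoinjuryZone.HOMOGENEOUS_NUCLEATION),
])
def test_cryoinjury_zones(t, zone):
    assert classify_zone(t) is zone


@settings(max_examples=200, deadline=None)
@given(st.floats(min_value=-200.0, max_value=60.0,
                 allow_nan=False, allow_infinity=False))
def test_zone_classification_total(t):
    assert classify_zone(t) in CryoinjuryZone
    # boundary consistency: values just above a boundary are in the warmer zone
    for b in (-40.0, -30.0, -20.0, -15.0, 0.0):
        assert classify_zone(b) is not classify_zone(b + 1e-6)


def _linear_radial_field(dom, slope=10.0, offset=-30.0):
    """T(r) = offset + slope * (r - lumen_radius) degC, everywhere."""
    r_mm = dom.r_centers * 1e3
    t = offset + slope * (r_mm - dom.pv.lumen_radius)
    return TemperatureField(dom, np.repeat(t[:, None], dom.nz, axis=1) + 273.15)


def test_extract_front_inverts_linear_profile():
    dom = build_domain(pv_parameters("right inferior"), resolution=0.2)
    fld = _linear_radial_field(dom)
    front = extract_front(fld, -15.0)
    assert front.shape[0] == dom.nz
    assert np.allclose(front[:, 0], dom.pv.lumen_radius + 1.5, atol=1e-9)


def test_front_nesting_colder_inside_warmer():
    dom = build_domain(pv_parameters("right inferior"), resolution=0.2)
    fld = _linear_radial_field(dom)
    f15 = extract_front(fld, -15.0)
    f0 = extract_front(fld, 0.0)
    assert np.all(f15[:, 0] <= f0[:, 0] + 1e-12)


def test_warm_field_has_empty_front():
    dom = build_domain(pv_parameters("right inferior"), resolution=0.3)
    fld = TemperatureField(dom, np.full((dom.nr, dom.nz), 36.7 + 273.15))
    assert extract_front(fld, -15.0).shape[0] == 0
    with pytest.warns(UserWarning):
        assert lesion_depth(np.empty((0, 2)),
                            dom.balloon_surface_points()) == 0.0


def test_front_matches_marching_squares():
    """Cross-check the per-ray front against skimage's contour extraction."""
    from skimage import measure

    dom = build_domain(pv_parameters("right inferior"), resolution=0.2)
    r = dom.r_centers[:, None] * 1e3
    z = dom.z_centers[None, :] * 1e3
    t = -40.0 + 4.0 * (r - 6.0) + 2.0 * np.sin(z / 8.0)
    fld = TemperatureField(dom, t + 273.15)
    mine = extract_front(fld, -15.0)
    contours = measure.find_contours(t, -15.0)
    ms = max(contours, key=len)
    ms_r = (ms[:, 0] + 0.5) * 0.2          # index -> mm
    ms_z = (ms[:, 1] + 0.5) * 0.2
    for rr, zz in mine[:: max(1, len(mine) // 40)]:
        j = np.argmin(np.abs(ms_z - zz))
        assert abs(ms_r[j] - rr) < 0.2     # within one cell


@pytest.mark.parametrize("offset,depth", [(2.14, 4.28), (1.62, 3.24)])
def test_lesion_depth_doubles_max_normal_distance(offset, depth):
    dom = build_domain(pv_parameters("left superior"), resolution=0.3)
    surface = dom.balloon_surface_points()
    equator_z = dom.balloon.axial_center
    front = np.array([[dom.pv.lumen_radius + offset, equator_z]])
    # tolerance reflects the density of the sampled surface polyline
    assert lesion_depth(front, surface) == pytest.approx(depth, abs=1e-3)


def test_lesion_area_formula():
    assert lesion_area(4.28, 23.0) == pytest.approx(
        math.pi * 2.14 * 11.5)
    assert lesion_area(0.0, 23.0) == 0.0
    with pytest.raises(ValueError):
        lesion_area(-1.0)
    with pytest.raises(ValueError):
        lesion_area(1.0, 0.0)


@pytest.mark.parametrize("depth,area", list(zip(TABLE_DEPTHS, TABLE_AREAS)))
def test_printed_area_convention(depth, area):
    assert printed_lesion_area(depth) == area


def test_summarize_population_sd():
    mean, sd = summarize(TABLE_DEPTHS)
    assert (round(mean, 2), round(sd, 2)) == (3.51, 0.51)
    mean, sd = summarize(TABLE_TM)
    assert (round(mean, 2), round(sd, 2)) == (35.20, 3.54)
    assert summarize([7.0]) == (7.0, 0.0)
    with pytest.raises(ValueError):
        summarize([])


def test_analyze_history_consistency(coarse_run):
    domain, schedule, history = coarse_run
    est = analyze_history(history, at_time=schedule.duration - 30.0,
                          patient_id="1", max_temperature=-60.0)
    assert est.width_B == 23.0
    assert est.area == pytest.approx(lesion_area(est.depth_A, 23.0))
    assert est.distance_balloon_to_outermost_front \
        == pytest.approx(est.depth_A / 2.0)
    assert est.depth_A > 0
    # the display (0 degC) contour encloses the -15 degC lesion front
    assert est.display_front_depth >= est.depth_A
    # colder threshold never yields a deeper front
    colder = analyze_history(history, threshold=-20.0,
                             at_time=schedule.duration - 30.0)
    assert colder.depth_A <= est.depth_A


def test_analyze_history_missing_snapshot(coarse_run):
    _, schedule, history = coarse_run
    with pytest.raises(ValueError, match="no snapshot"):
        analyze_history(history, at_time=10_000.0)


def test_summarize_therapies_builds_cohort_table():
    from cryopvi.lesion import LesionEstimate

    ests = [LesionEstimate(depth_A=d, area=lesion_area(d),
                           patient_id=str(i + 1), max_temperature=-50.0)
            for i, d in enumerate(TABLE_DEPTHS)]
    summary = summarize_therapies(ests, time_to_isolation=TABLE_TM)
    m, s = summary.statistics["lesion_depth_mm"]
    assert (round(m, 2), round(s, 2)) == (3.51, 0.51)
    m, s = summary.statistics["time_to_isolation_s"]
    assert (round(m, 2), round(s, 2)) == (35.20, 3.54)
    assert len(summary.records) == 5
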