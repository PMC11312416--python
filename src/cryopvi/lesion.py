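"""Lesion quantification: isotherm fronts, depth/area, cryoinjury zones, stats.

Lesion size is measured from the -15 degC isotherm — the temperature below
which ice crystals nucleate in the extracellular space — at the end of the
final freeze.  Depth A is twice the largest normal distance from the balloon
surface to that front; width B is fixed at 23 mm (the inflated balloon
diameter, reflecting the uniform equatorial cooling band of the
second-generation cryoballoon); the cross-section area follows the ellipse
formula

    area = pi * (A / 2) * (B / 2).

The 0 degC contour is retained as the display boundary of affected tissue.
Cohort statistics use the population (divisor-n) standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import numpy as np

from .materials import CELSIUS_OFFSET, ComputationalDomain
from .solver import TemperatureField, TemperatureHistory

LESION_THRESHOLD_C = -15.0
DISPLAY_THRESHOLD_C = 0.0
LESION_WIDTH_MM = 23.0


def kelvin_to_celsius(t: float | np.ndarray) -> float | np.ndarray:
    """Kelvin to Celsius; rejects negative absolute temperatures."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("absolute temperature cannot be negative")
    out = t - CELSIUS_OFFSET
    return float(out) if out.ndim == 0 else out


def celsius_to_kelvin(t: float | np.ndarray) -> float | np.ndarray:
    t = np.asarray(t, dtype=float)
    out = t + CELSIUS_OFFSET
    return float(out) if out.ndim == 0 else out


class CryoinjuryZone(Enum):
    """Histophysiological response bands of freezing tissue.

    Between 0 and -15 degC the cell membrane still blocks ice nucleation;
    below -15 degC extracellular ice forms (heterogeneous nucleation); between
    -20 and -30 degC intracellular ice appears as vascular equilibrium is
    reached; -30 degC marks the vasoconstriction response; at and below
    -40 degC intra- and extracellular crystal clusters form simultaneously
    (homogeneous nucleation) and cell death is irreversible.
    """

    ABOVE_FREEZING = "above_freezing"
    MEMBRANE_RESISTANT = "membrane_resistant"
    EXTRACELLULAR_ICE = "extracellular_ice"
    INTRACELLULAR_ICE = "intracellular_ice"
    VASOCONSTRICTION_MARKER = "vasoconstriction_marker"
    HOMOGENEOUS_NUCLEATION = "homogeneous_nucleation"


#: Zone lower bounds (degC, inclusive: a boundary belongs to the colder zone).
ZONE_UPPER_BOUNDS = [
    (-40.0, CryoinjuryZone.HOMOGENEOUS_NUCLEATION),
    (-30.0, CryoinjuryZone.VASOCONSTRICTION_MARKER),
    (-20.0, CryoinjuryZone.INTRACELLULAR_ICE),
    (-15.0, CryoinjuryZone.EXTRACELLULAR_ICE),
    (0.0, CryoinjuryZone.MEMBRANE_RESISTANT),
]


def classify_zone(temperature_C: float) -> CryoinjuryZone:
    """Cryoinjury zone of a temperature; boundaries belong to the colder zone."""
    t = float(temperature_C)
    if not math.isfinite(t):
        raise ValueError("temperature must be finite")
    for bound, zone in ZONE_UPPER_BOUNDS:
        if t <= bound:
            return zone
    return CryoinjuryZone.ABOVE_FREEZING


def extract_front(field: TemperatureField, threshold: float = LESION_THRESHOLD_C
                  ) -> np.ndarray:
    """Outermost isotherm points within tissue, shape (m, 2) of (r_mm, z_mm).

    For each axial row the outermost tissue cell at or below the threshold is
    located and the crossing radius found by linear interpolation to the next
    (warmer) tissue cell.  Rows with no sub-threshold tissue contribute no
    point; an empty array is a valid result.
    """
    dom = field.domain
    tc = field.celsius
    tissue = dom.tissue_mask
    r_mm = dom.r_centers * 1e3
    z_mm = dom.z_centers * 1e3
    pts = []
    for j in range(dom.nz):
        col = tissue[:, j]
        if not col.any():
            continue
        rows = np.nonzero(col)[0]
        temps = tc[rows, j]
        below = np.nonzero(temps <= threshold)[0]
        if below.size == 0:
            continue
        i = below[-1]
        if i + 1 < rows.size:
            t0, t1 = temps[i], temps[i + 1]
            frac = 0.0 if t1 == t0 else (threshold - t0) / (t1 - t0)
            r_cross = r_mm[rows[i]] + frac * (r_mm[rows[i + 1]] - r_mm[rows[i]])
        else:
            r_cross = r_mm[rows[i]]     # front clamped at the outer boundary
        pts.append((r_cross, z_mm[j]))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def lesion_depth(front: np.ndarray, balloon_surface: np.ndarray) -> float:
    """Lesion depth A (mm): twice the largest normal distance to the front.

    ``balloon_surface`` is a dense (k, 2) polyline of the clipped balloon
    surface in (r, z) mm; the normal distance of each front point is its
    minimum distance to that polyline.
    """
    front = np.asarray(front, dtype=float).reshape(-1, 2)
    if front.shape[0] == 0:
        warnings.warn("empty isotherm front; lesion depth is 0", stacklevel=2)
        return 0.0
    d = np.sqrt(((front[:, None, :] - balloon_surface[None, :, :]) ** 2
                 ).sum(axis=2)).min(axis=1)
    return 2.0 * float(d.max())


def lesion_area(depth_A: float, width_B: float = LESION_WIDTH_MM) -> float:
    """Elliptical lesion cross-section area (mm^2): pi * (A/2) * (B/2)."""
    if depth_A < 0:
        raise ValueError("lesion depth must be >= 0")
    if width_B <= 0:
        raise ValueError("lesion width must be > 0")
    return math.pi * (depth_A / 2.0) * (width_B / 2.0)


def printed_lesion_area(depth_A: float, width_B: float = LESION_WIDTH_MM) -> float:
    """Ellipse area under the reporting convention of the source cohort table:
    pi evaluated to two decimals (3.14) and the result rounded half-up to two
    decimals.  Exact decimal arithmetic avoids binary-float rounding artifacts
    (e.g. 54.165 must round to 54.17, not 54.16)."""
    v = (Decimal("3.14") * Decimal(str(depth_A)) / 2
         * Decimal(str(width_B)) / 2)
    return float(v.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and population (divisor-n) standard deviation."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    return float(arr.mean()), float(arr.std(ddof=0))


@dataclass(frozen=True)
class LesionEstimate:
    """Isotherm-derived lesion measurements for one therapy."""

    threshold: float = LESION_THRESHOLD_C
    depth_A: float = 0.0
    width_B: float = LESION_WIDTH_MM
    area: float = 0.0
    distance_balloon_to_wall: float = 0.0
    distance_balloon_to_outermost_front: float = 0.0
    display_front_depth: float = 0.0     # 0 degC contour, display boundary
    patient_id: str = ""
    max_temperature: float = float("nan")
    evaluated_at_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.depth_A < 0:
            raise ValueError("depth_A must be >= 0")


@dataclass
class TherapySummary:
    """Per-patient lesion records with cohort mean +/- population SD."""

    records: list[dict]
    statistics: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("cohort must contain at least one record")
        if not self.statistics:
            keys = [k for k, v in self.records[0].items()
                    if isinstance(v, (int, float))]
            self.statistics = {
                k: summarize([r[k] for r in self.records]) for k in keys}


def analyze_history(history: TemperatureHistory,
                    threshold: float = LESION_THRESHOLD_C,
                    display_threshold: float = DISPLAY_THRESHOLD_C,
                    at_time: float | None = None,
                    patient_id: str = "",
                    max_temperature: float = float("nan")) -> LesionEstimate:
    """Measure the lesion at the end of the final freeze (default: last snapshot).

    Returns depth (twice the deepest -15 degC front penetration beyond the
    balloon surface), the fixed 23 mm width, the ellipse area with
    full-precision pi, and the balloon-to-wall / balloon-to-front diagnostic
    distances.
    """
    dom = history.domain
    fld = history.final_field if at_time is None else history.field_at(at_time)
    if at_time is not None:
        gaps = np.diff(history.snapshot_times)
        tol = float(gaps.max()) / 2.0 + 1e-9 if gaps.size else 1e-6
        if abs(fld.time - at_time) > tol:
            raise ValueError(f"no snapshot near t={at_time} s "
                             f"(nearest: {fld.time} s)")
    surface = dom.balloon_surface_points()
    front = extract_front(fld, threshold)

    if front.shape[0] == 0:
        depth = 0.0
        dist_front = 0.0
        dist_wall = 0.0
    else:
        dists = np.sqrt(((front[:, None, :] - surface[None, :, :]) ** 2
                         ).sum(axis=2)).min(axis=1)
        imax = int(np.argmax(dists))
        dist_front = float(dists[imax])
        depth = 2.0 * dist_front
        # Diagnostic: balloon-to-vascular-wall distance at the axial level
        # of deepest penetration (the cohort table's construction for this
        # column is unpublished; here it is the distance to the nearest
        # wall-labeled cell center in that axial column).
        from .materials import LABEL_WALL
        j_deep = int(np.argmin(np.abs(dom.z_centers * 1e3 - front[imax, 1])))
        wall_rows = np.nonzero(dom.labels[:, j_deep] == LABEL_WALL)[0]
        if wall_rows.size:
            wall_pt = np.array([[dom.r_centers[wall_rows[0]] * 1e3,
                                 dom.z_centers[j_deep] * 1e3]])
            dist_wall = float(np.sqrt(((wall_pt - surface) ** 2
                                       ).sum(axis=1)).min())
        else:
            dist_wall = 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        display_front = extract_front(fld, display_threshold)
        display_depth = lesion_depth(display_front, surface) \
            if display_front.shape[0] else 0.0

    return LesionEstimate(
        threshold=threshold, depth_A=depth, width_B=LESION_WIDTH_MM,
        area=lesion_area(depth, LESION_WIDTH_MM),
        distance_balloon_to_wall=dist_wall,
        distance_balloon_to_outermost_front=dist_front,
        display_front_depth=display_depth,
        patient_id=patient_id, max_temperature=max_temperature,
        evaluated_at_s=float(fld.time))


def summarize_therapies(estimates: list[LesionEstimate],
                        time_to_isolation: list[float] | None = None
                        ) -> TherapySummary:
    """Cohort summary across per-patient lesion estimates."""
    records = []
    for i, e in enumerate(estimates):
        rec = {
            "patient_id": e.patient_id,
            "max_freezing_temperature_C": e.max_temperature,
            "distance_balloon_to_wall_mm": e.distance_balloon_to_wall,
            "lesion_depth_mm": e.depth_A,
            "lesion_area_mm2": e.area,
        }
        if time_to_isolation is not None:
            rec["time_to_isolation_s"] = float(time_to_isolation[i])
        records.append(rec)
    stats = {k: summarize([r[k] for r in records])
             for k in records[0] if k != "patient_id"
             and np.isfinite([r[k] for r in records]).all()}
    return TherapySummary(records=records, statistics=stats)
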