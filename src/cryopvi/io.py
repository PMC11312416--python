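"""File exports and reports: field CSV/VTK, lesion reports, provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lesion import LesionEstimate, TherapySummary, summarize
from .solver import TemperatureField, TemperatureHistory

COHORT_COLUMNS = [
    "patient_id", "max_freezing_temperature_C",
    "distance_balloon_to_wall_mm", "lesion_depth_mm", "lesion_area_mm2",
    "time_to_isolation_s",
]


def field_to_frame(field: TemperatureField) -> pd.DataFrame:
    """Long-format (time, r_mm, z_mm, label, temperature_C) table."""
    dom = field.domain
    r, z = np.meshgrid(dom.r_centers * 1e3, dom.z_centers * 1e3, indexing="ij")
    return pd.DataFrame({
        "time_s": field.time,
        "r_mm": r.ravel(), "z_mm": z.ravel(),
        "label": dom.labels.ravel(),
        "temperature_C": field.celsius.ravel(),
    })


def export_field_csv(field: TemperatureField, path: str | Path) -> None:
    field_to_frame(field).to_csv(path, index=False)


def export_history_csv(history: TemperatureHistory, path: str | Path) -> None:
    frames = [field_to_frame(TemperatureField(history.domain, s, time=t))
              for t, s in zip(history.snapshot_times, history.snapshots)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def export_vtk(field: TemperatureField, path: str | Path) -> None:
    """Legacy-ASCII VTK structured grid of the (r, z) plane (y = 0)."""
    dom = field.domain
    r = dom.r_centers
    z = dom.z_centers
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n"
                 f"cryopvi temperature field t={field.time} s\n"
                 "ASCII\nDATASET STRUCTURED_GRID\n"
                 f"DIMENSIONS {dom.nr} {dom.nz} 1\n"
                 f"POINTS {dom.nr * dom.nz} float\n")
        for zz in z:
            for rr in r:
                fh.write(f"{rr:.8e} 0.0 {zz:.8e}\n")
        fh.write(f"POINT_DATA {dom.nr * dom.nz}\n"
                 "SCALARS temperature_C float 1\nLOOKUP_TABLE default\n")
        for j in range(dom.nz):
            for i in range(dom.nr):
                fh.write(f"{field.celsius[i, j]:.6f}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        for j in range(dom.nz):
            for i in range(dom.nr):
                fh.write(f"{int(dom.labels[i, j])}\n")


def write_lesion_report(summary: TherapySummary, path: str | Path) -> None:
    """JSON report: per-patient records plus cohort mean +/- population SD."""
    payload = {
        "records": summary.records,
        "cohort": {k: {"mean": m, "sd": s}
                   for k, (m, s) in summary.statistics.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_lesion_report(path: str | Path) -> TherapySummary:
    data = json.loads(Path(path).read_text())
    if "records" not in data or not data["records"]:
        raise ValueError(f"malformed lesion report: {path}")
    return TherapySummary(records=data["records"])


def write_cohort_csv(summary: TherapySummary, path: str | Path) -> None:
    """CSV mirroring the cohort results table's columns."""
    df = pd.DataFrame(summary.records)
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_provenance(config_text: str, path: str | Path) -> None:
    """Record the exact configuration and library versions of a run."""
    import scipy

    from . import __version__
    payload = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "config": config_text,
        "versions": {
            "cryopvi": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
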