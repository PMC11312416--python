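"""Therapy logs and the balloon surface-temperature schedule.

A cryoballoon therapy log records four thermocouple milestones: TZ, the time
the balloon reading crosses 0 degC; TI, the time it reaches -30 degC; TM, the
time of maximum cold (time to isolation); and TT, the total therapy time
including rewarming back to body temperature.  Two freeze/thaw cycles are
administered per vein, and since only one milestone set is recorded per
patient the second cycle duplicates the first.

The schedule interpolates the milestones piecewise-linearly, holds the
maximum cold until ``TT - rewarm_duration``, then rewarms linearly to body
temperature (36.7 degC) at TT.  It drives the balloon-region Dirichlet
boundary condition of the solver.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .materials import BODY_TEMPERATURE_C

LOG_COLUMNS = ["patient_id", "TZ", "TI", "TM", "max_temperature", "TT"]


@dataclass(frozen=True)
class TherapyLog:
    """One patient's milestone record (times s, temperature degC)."""

    patient_id: str
    TZ: float
    TI: float
    TM: float
    max_temperature: float
    TT: float = 240.0
    cycles: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.TZ < self.TI < self.TM < self.TT:
            raise ValueError(
                f"patient {self.patient_id}: milestone times must satisfy "
                f"0 < TZ < TI < TM < TT, got TZ={self.TZ}, TI={self.TI}, "
                f"TM={self.TM}, TT={self.TT}")
        if self.max_temperature > -30.0:
            raise ValueError(
                f"patient {self.patient_id}: max freezing temperature must be "
                f"<= -30 degC, got {self.max_temperature}")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")


@dataclass(frozen=True)
class BalloonTemperatureSchedule:
    """Piecewise-linear balloon surface temperature over the concatenated cycles."""

    times: np.ndarray          # breakpoint times, s, strictly increasing
    temperatures: np.ndarray   # degC at each breakpoint
    cycle_duration: float
    cycles: int

    @property
    def duration(self) -> float:
        return self.cycle_duration * self.cycles

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return schedule_value(self, t)

    @property
    def minimum(self) -> float:
        return float(self.temperatures.min())


def build_schedule(log: TherapyLog, rewarm_duration: float = 30.0
                   ) -> BalloonTemperatureSchedule:
    """Convert milestone records into the two-cycle boundary schedule.

    Per cycle: (0, 36.7) -> (TZ, 0) -> (TI, -30) -> (TM, max) -> hold at max
    until TT - rewarm_duration -> (TT, 36.7); cycles concatenated end-to-end.
    """
    if not rewarm_duration < log.TT - log.TM:
        raise ValueError(
            f"rewarm_duration {rewarm_duration} s must be < TT - TM = "
            f"{log.TT - log.TM} s")
    base_t = [0.0, log.TZ, log.TI, log.TM, log.TT - rewarm_duration, log.TT]
    base_T = [BODY_TEMPERATURE_C, 0.0, -30.0, log.max_temperature,
              log.max_temperature, BODY_TEMPERATURE_C]
    times, temps = [], []
    for c in range(log.cycles):
        offset = c * log.TT
        start = 0 if c == 0 else 1   # cycle start coincides with previous end
        times.extend(offset + t for t in base_t[start:])
        temps.extend(base_T[start:])
    return BalloonTemperatureSchedule(
        times=np.asarray(times, dtype=float),
        temperatures=np.asarray(temps, dtype=float),
        cycle_duration=float(log.TT), cycles=log.cycles)


def schedule_value(schedule: BalloonTemperatureSchedule,
                   t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the schedule (degC) by linear interpolation; errors out of range."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > schedule.duration + 1e-9):
        raise ValueError(
            f"time {t} s outside schedule range [0, {schedule.duration}] s")
    out = np.interp(t_arr, schedule.times, schedule.temperatures)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def read_therapy_log(source, cycles: int = 2) -> list[TherapyLog]:
    """Read and validate a therapy-log table (CSV path, buffer, or DataFrame).

    Every row must carry the header columns
    ``patient_id,TZ,TI,TM,max_temperature,TT``; rows violating the milestone
    invariants are rejected with row-level diagnostics.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"therapy log missing column(s): {', '.join(missing)}")

    logs, errors = [], []
    for idx in df.index:
        # column-wise access keeps patient_id's own dtype (iterrows upcasts)
        try:
            logs.append(TherapyLog(
                patient_id=str(df.at[idx, "patient_id"]),
                TZ=float(df.at[idx, "TZ"]), TI=float(df.at[idx, "TI"]),
                TM=float(df.at[idx, "TM"]),
                max_temperature=float(df.at[idx, "max_temperature"]),
                TT=float(df.at[idx, "TT"]), cycles=cycles))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValueError("invalid therapy log rows:\n" + "\n".join(errors))
    return logs


def write_therapy_log(logs: list[TherapyLog], path: str | Path | io.IOBase) -> None:
    """Write logs back to CSV (lossless round-trip with read_therapy_log)."""
    logs_to_frame(logs).to_csv(path, index=False)


def logs_to_frame(logs: list[TherapyLog]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(log, c) for c in LOG_COLUMNS} for log in logs])


def packaged_table_path() -> Path:
    """Path of the packaged five-patient therapy-log fixture."""
    return Path(__file__).parent / "data" / "therapy_logs.csv"


def load_packaged_logs(cycles: int = 2) -> list[TherapyLog]:
    """The five in-cohort patient logs shipped with the package."""
    return read_therapy_log(packaged_table_path(), cycles=cycles)
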