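"""Domain types, file I/O, window segmentation and recording-level quality control.

An ambulatory blood pressure monitoring (ABPM) recording is an ordered series
of cuff readings (SBP/DBP, optionally heart rate) spanning a nominal 24-h
monitoring day, together with a sleep diary giving the wearer's wake and bed
times.  Daytime and night-time windows are defined from the diary, not from
fixed clock times: daytime runs from the time the wearer rose until they
retired to bed, night-time is the complement.

Quality control follows the usual ABPM screening rules: a recording is
discarded when fewer than 80% of the scheduled readings are valid or when a
full hour of data is missing (operationalised here as any gap longer than
60 minutes between consecutive valid readings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "BPReading",
    "SleepDiary",
    "ABPMRecording",
    "WindowedRecording",
    "QCReport",
    "Schedule",
    "load_recordings",
    "write_recordings",
    "segment_windows",
    "qc_validity",
]

#: Ordered study visits: before training, after training, after detraining.
TIMEPOINTS = ("baseline", "mid", "end")

_TS_FORMAT = "%Y-%m-%dT%H:%M"


@dataclass(frozen=True)
class BPReading:
    """One automated cuff measurement.

    ``valid`` mirrors the device-accepted flag; physiologically implausible
    readings (``sbp <= dbp``) are retained but flagged invalid rather than
    dropped, so QC counts reflect the device record.
    """

    timestamp: datetime
    sbp: float
    dbp: float
    hr: float | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        if not (self.sbp > 0 and self.dbp > 0):
            raise ValueError(f"non-positive pressure in reading at {self.timestamp}")
        if self.hr is not None and not self.hr > 0:
            raise ValueError(f"non-positive heart rate in reading at {self.timestamp}")


@dataclass(frozen=True)
class SleepDiary:
    """Self-reported wake and bed times for one monitoring day."""

    wake_time: datetime
    bed_time: datetime

    def __post_init__(self) -> None:
        day = self.bed_time - self.wake_time
        if not timedelta(hours=8) < day < timedelta(hours=22):
            raise ValueError(
                f"implausible diary: awake interval {day} outside (8 h, 22 h)"
            )

    @property
    def day_duration(self) -> timedelta:
        return self.bed_time - self.wake_time

    @property
    def night_duration(self) -> timedelta:
        """Night span of the nominal 24-h monitoring day (bed to next wake)."""
        return timedelta(hours=24) - self.day_duration

    @property
    def next_wake(self) -> datetime:
        return self.wake_time + timedelta(hours=24)


@dataclass
class ABPMRecording:
    """One subject-visit: time-sorted readings plus the sleep diary."""

    subject_id: str
    timepoint: str
    readings: list[BPReading]
    diary: SleepDiary

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        if len(self.readings) < 2:
            raise ValueError(
                f"recording {self.subject_id}/{self.timepoint} has "
                f"{len(self.readings)} readings; need at least 2"
            )
        self.readings = sorted(self.readings, key=lambda r: r.timestamp)

    def timestamps(self) -> np.ndarray:
        return np.array([r.timestamp for r in self.readings], dtype="datetime64[s]")

    def channel(self, name: str) -> np.ndarray:
        if name not in ("sbp", "dbp", "hr"):
            raise ValueError(f"unknown channel {name!r}")
        return np.array(
            [getattr(r, name) if getattr(r, name) is not None else np.nan
             for r in self.readings],
            dtype=float,
        )

    def valid_mask(self) -> np.ndarray:
        return np.array([r.valid for r in self.readings], dtype=bool)


@dataclass
class WindowedRecording:
    """A recording with daytime / night-time index sets.

    ``day_idx`` and ``night_idx`` partition ``all_idx`` exactly; a reading at
    the bed-time minute belongs to the night window (half-open daytime
    interval ``[wake, bed)``), and readings taken before the first waking are
    assigned to night.
    """

    recording: ABPMRecording
    day_idx: np.ndarray
    night_idx: np.ndarray
    all_idx: np.ndarray

    @property
    def diary(self) -> SleepDiary:
        return self.recording.diary

    def window_indices(self, window: str) -> np.ndarray:
        try:
            return {"24h": self.all_idx, "day": self.day_idx, "night": self.night_idx}[
                window
            ]
        except KeyError:
            raise ValueError(
                f"unknown window {window!r}; expected '24h', 'day' or 'night'"
            ) from None


@dataclass(frozen=True)
class QCReport:
    """Outcome of the screening rules applied to one recording."""

    n_expected: int
    n_valid: int
    valid_fraction: float
    max_gap_minutes: float
    has_missing_hour: bool
    passed: bool


@dataclass(frozen=True)
class Schedule:
    """Nominal monitor programming: reading cadence by window.

    Default cadence is a reading every 30 min while awake and hourly during
    sleep, the usual programming of 24-h monitors in exercise-training trials.
    """

    day_cadence_min: int = 30
    night_cadence_min: int = 60

    def expected_count(self, diary: SleepDiary) -> int:
        day_min = diary.day_duration.total_seconds() / 60.0
        night_min = diary.night_duration.total_seconds() / 60.0
        return int(day_min // self.day_cadence_min) + int(
            night_min // self.night_cadence_min
        )


# ---------------------------------------------------------------------------
# Segmentation and QC
# ---------------------------------------------------------------------------


def segment_windows(rec: ABPMRecording) -> WindowedRecording:
    """Partition a recording into daytime and night-time index sets.

    Daytime is the half-open interval [wake, bed) of each monitoring day;
    everything else (readings at/after bed time, and any readings before the
    first waking) is night.  Readings on the following day are folded onto
    the same clock windows, so a recording running past the next waking keeps
    a consistent partition.
    """
    if rec.diary is None:  # pragma: no cover - dataclass requires a diary
        raise ValueError("recording has no sleep diary; cannot segment")
    wake, bed = rec.diary.wake_time, rec.diary.bed_time
    ts = [r.timestamp for r in rec.readings]
    day = np.zeros(len(ts), dtype=bool)
    for k, t in enumerate(ts):
        # fold onto the first monitoring day's clock
        u = t
        while u >= wake + timedelta(hours=24):
            u -= timedelta(hours=24)
        day[k] = wake <= u < bed
    if not (min(ts) <= rec.diary.next_wake and max(ts) >= wake):
        raise ValueError(
            f"all readings of {rec.subject_id}/{rec.timepoint} fall outside "
            f"the diary's monitoring day"
        )
    all_idx = np.arange(len(ts))
    return WindowedRecording(
        recording=rec,
        day_idx=all_idx[day],
        night_idx=all_idx[~day],
        all_idx=all_idx,
    )


def qc_validity(rec: ABPMRecording, schedule: Schedule | None = None) -> QCReport:
    """Apply the 80%-valid and missing-hour screening rules.

    The expected reading count is derived from the diary durations and the
    nominal cadence (not from the device file), so the 80% rule is comparable
    across subjects.  ``has_missing_hour`` is true when any gap between
    consecutive valid readings exceeds 60 minutes; the rule is schedule
    independent.
    """
    schedule = schedule or Schedule()
    n_expected = schedule.expected_count(rec.diary)
    if n_expected == 0:
        raise ValueError("diary durations imply zero expected readings")
    valid_ts = [r.timestamp for r in rec.readings if r.valid]
    n_valid = len(valid_ts)
    if len(valid_ts) >= 2:
        gaps = np.diff(np.array(valid_ts, dtype="datetime64[s]")).astype(float) / 60.0
        max_gap = float(gaps.max())
    else:
        max_gap = float(rec.diary.night_duration.total_seconds() / 60.0) + 61.0
    has_missing_hour = max_gap > 60.0
    valid_fraction = min(1.0, n_valid / n_expected)
    passed = valid_fraction >= 0.80 and not has_missing_hour
    return QCReport(
        n_expected=n_expected,
        n_valid=n_valid,
        valid_fraction=valid_fraction,
        max_gap_minutes=max_gap,
        has_missing_hour=has_missing_hour,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
#
# Readings CSV: subject_id,timepoint,timestamp,sbp,dbp,hr,valid
# Diary CSV:    subject_id,timepoint,wake_time,bed_time
# Timestamps are ISO-8601 at minute precision, timezone-naive local clock.


def _parse_ts(value: str, *, row: int, column: str) -> datetime:
    try:
        return datetime.strptime(str(value), _TS_FORMAT)
    except ValueError as exc:
        raise ValueError(
            f"malformed timestamp {value!r} in column {column!r}, row {row}"
        ) from exc


def load_recordings(path: str | Path, diary_path: str | Path) -> list[ABPMRecording]:
    """Read a readings CSV and a diary CSV into recordings.

    Readings are grouped by (subject_id, timepoint) and time-sorted.  Rows
    with ``dbp >= sbp`` are retained but re-flagged invalid with a warning.
    Diaries without a matching recording are reported with a warning.
    """
    readings_df = pd.read_csv(
        path, dtype={"subject_id": str}, float_precision="round_trip"
    )
    diary_df = pd.read_csv(diary_path, dtype={"subject_id": str})
    diaries: dict[tuple[str, str], SleepDiary] = {}
    for i, row in diary_df.iterrows():
        diaries[(row["subject_id"], row["timepoint"])] = SleepDiary(
            wake_time=_parse_ts(row["wake_time"], row=i, column="wake_time"),
            bed_time=_parse_ts(row["bed_time"], row=i, column="bed_time"),
        )

    grouped: dict[tuple[str, str], list[BPReading]] = {}
    for i, row in readings_df.iterrows():
        ts = _parse_ts(row["timestamp"], row=i, column="timestamp")
        sbp, dbp = float(row["sbp"]), float(row["dbp"])
        valid = bool(int(row["valid"]))
        if sbp <= dbp:
            if valid:
                warnings.warn(
                    f"row {i}: sbp {sbp} <= dbp {dbp}; reading flagged invalid",
                    stacklevel=2,
                )
            valid = False
        hr = row.get("hr", np.nan)
        hr = None if pd.isna(hr) else float(hr)
        key = (row["subject_id"], row["timepoint"])
        grouped.setdefault(key, []).append(
            BPReading(timestamp=ts, sbp=sbp, dbp=dbp, hr=hr, valid=valid)
        )

    recs = []
    for (sid, tp), rows in grouped.items():
        if (sid, tp) not in diaries:
            raise ValueError(f"no diary for recording {sid}/{tp}")
        recs.append(
            ABPMRecording(subject_id=sid, timepoint=tp, readings=rows,
                          diary=diaries[(sid, tp)])
        )
    unmatched = set(diaries) - set(grouped)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} diary entries without readings: {sorted(unmatched)}",
            stacklevel=2,
        )
    return recs


def write_recordings(
    recs: Iterable[ABPMRecording],
    path: str | Path,
    diary_path: str | Path | None = None,
) -> None:
    """Write recordings (and optionally their diaries) back to CSV.

    Values and flags round-trip bit-identically through ``load_recordings``.
    """
    rows = []
    diary_rows = []
    for rec in recs:
        for r in rec.readings:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "timepoint": rec.timepoint,
                    "timestamp": r.timestamp.strftime(_TS_FORMAT),
                    # repr round-trips float64 exactly through read_csv
                    "sbp": repr(r.sbp),
                    "dbp": repr(r.dbp),
                    "hr": "" if r.hr is None else repr(r.hr),
                    "valid": int(r.valid),
                }
            )
        diary_rows.append(
            {
                "subject_id": rec.subject_id,
                "timepoint": rec.timepoint,
                "wake_time": rec.diary.wake_time.strftime(_TS_FORMAT),
                "bed_time": rec.diary.bed_time.strftime(_TS_FORMAT),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\r\n")
    if diary_path is not None:
        pd.DataFrame(diary_rows).to_csv(diary_path, index=False, lineterminator="\r\n")
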