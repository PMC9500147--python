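"""Scalar blood-pressure statistics derived from one ABPM recording.

Implements the per-recording measures used in ambulatory BP trials:

* resting BP selection — the lowest of three seated/supine triplicate
  readings per channel, with MAP recomputed from the selected values;
* window means — arithmetic mean of valid readings over the 24-h, daytime
  and night-time windows;
* sleep-trough morning BP surge (MBPS) — mean SBP in the 2 h after waking
  minus the mean of a small set of readings around the lowest nocturnal SBP;
* average real variability (ARV) — the mean absolute difference between
  successive readings, optionally weighted by the time between them;
* nocturnal dip — percentage fall of the night-time SBP mean relative to day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from datetime import timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ABPMRecording,
    BPReading,
    Schedule,
    WindowedRecording,
    qc_validity,
    segment_windows,
)

__all__ = [
    "RestingResult",
    "MBPSResult",
    "MetricsRow",
    "resting_bp",
    "window_mean",
    "morning_surge",
    "average_real_variability",
    "nocturnal_dip",
    "compute_metrics",
    "metrics_table",
    "TROUGH_RULES",
]

#: Supported definitions of the nocturnal trough set used by the surge:
#: ``lowest2``  — lowest reading plus its smaller-valued adjacent neighbour;
#: ``kario3``  — lowest reading plus both adjacent neighbours;
#: ``lowest1`` — the single lowest reading.
TROUGH_RULES = ("lowest2", "kario3", "lowest1")


@dataclass(frozen=True)
class RestingResult:
    """Per-channel minima over a resting triplet, with recomputed MAP."""

    sbp: float
    dbp: float
    map: float
    hr: float | None


@dataclass(frozen=True)
class MBPSResult:
    morning_mean: float
    trough_mean: float
    surge: float
    n_morning: int
    trough_timestamps: tuple
    low_confidence: bool = False


@dataclass
class MetricsRow:
    """All derived scalars for one recording."""

    subject_id: str
    timepoint: str
    mean_24h_sbp: float
    mean_24h_dbp: float
    mean_day_sbp: float
    mean_day_dbp: float
    mean_night_sbp: float
    mean_night_dbp: float
    arv_24h_sbp: float
    arv_day_sbp: float
    arv_night_sbp: float
    arv_24h_dbp: float
    arv_day_dbp: float
    arv_night_dbp: float
    mbps: float
    morning_sbp: float
    lowest_night_sbp: float
    dip_pct: float
    qc_passed: bool

    def to_dict(self) -> dict:
        return asdict(self)


def resting_bp(triplet: Sequence[BPReading]) -> RestingResult:
    """Select resting BP from a triplicate measurement.

    Takes the per-channel minimum across exactly three readings (the lowest
    SBP, the lowest DBP and, when present, the lowest HR need not come from
    the same reading) and recomputes MAP as ``dbp + (sbp - dbp)/3`` from the
    selected pressures.
    """
    if len(triplet) != 3:
        raise ValueError(f"resting BP requires exactly 3 readings, got {len(triplet)}")
    sbp = min(r.sbp for r in triplet)
    dbp = min(r.dbp for r in triplet)
    hrs = [r.hr for r in triplet if r.hr is not None]
    hr = min(hrs) if hrs else None
    return RestingResult(sbp=sbp, dbp=dbp, map=dbp + (sbp - dbp) / 3.0, hr=hr)


def _window_values(
    w: WindowedRecording, window: str, channel: str
) -> tuple[np.ndarray, np.ndarray]:
    """Valid readings' values and timestamps (as datetime64[s]) in a window."""
    idx = w.window_indices(window)
    values = w.recording.channel(channel)[idx]
    valid = w.recording.valid_mask()[idx] & ~np.isnan(values)
    ts = w.recording.timestamps()[idx]
    return values[valid], ts[valid]


def window_mean(w: WindowedRecording, window: str, channel: str) -> float:
    """Arithmetic mean of valid readings in the requested window."""
    values, _ = _window_values(w, window, channel)
    if values.size == 0:
        raise ValueError(f"no valid {channel} readings in {window} window")
    return float(values.mean())


def morning_surge(
    w: WindowedRecording, trough_rule: str = "lowest2"
) -> MBPSResult:
    """Sleep-trough morning blood pressure surge.

    ``morning_mean`` averages all valid SBP readings in the half-open 2-h
    window just after waking (nominally four readings at a 30-min cadence; a
    warning is raised when the count differs).  The trough set is controlled
    by ``trough_rule``; the default two-reading rule pairs the lowest
    nocturnal reading with its smaller-valued time-adjacent neighbour
    (earlier neighbour on a tie).  The surge is not normalised to the 24-h
    mean.
    """
    if trough_rule not in TROUGH_RULES:
        raise ValueError(f"unknown trough_rule {trough_rule!r}; use one of {TROUGH_RULES}")
    wake = w.diary.wake_time
    values = w.recording.channel("sbp")
    ts = [r.timestamp for r in w.recording.readings]
    valid = w.recording.valid_mask()

    morning_idx = [
        k
        for k in w.day_idx
        if valid[k] and wake <= ts[k] < wake + timedelta(hours=2)
    ]
    if not morning_idx:
        raise ValueError("no valid SBP readings in the 2-h post-wake window")
    morning = values[morning_idx]
    n_morning = len(morning_idx)
    if n_morning != 4:
        warnings.warn(
            f"{n_morning} readings in the 2-h post-wake window (expected 4)",
            stacklevel=2,
        )
    low_confidence = n_morning < 2

    night_idx = [k for k in w.night_idx if valid[k]]
    if not night_idx:
        raise ValueError("no valid nocturnal SBP readings")
    if len(night_idx) < 2 and trough_rule != "lowest1":
        raise ValueError("need at least 2 valid nocturnal readings for the trough set")
    night_vals = values[night_idx]
    j = int(np.argmin(night_vals))  # first minimum on ties (earliest)
    trough_set = [night_idx[j]]
    if trough_rule != "lowest1":
        neighbours = [night_idx[k] for k in (j - 1, j + 1) if 0 <= k < len(night_idx)]
        if trough_rule == "kario3":
            trough_set += neighbours
        else:  # lowest2: smaller-valued neighbour, earlier on tie
            neighbours.sort(key=lambda k: (values[k], ts[k]))
            trough_set.append(neighbours[0])
    trough_set.sort()
    trough = values[trough_set]
    morning_mean = float(morning.mean())
    trough_mean = float(trough.mean())
    return MBPSResult(
        morning_mean=morning_mean,
        trough_mean=trough_mean,
        surge=morning_mean - trough_mean,
        n_morning=n_morning,
        trough_timestamps=tuple(ts[k] for k in trough_set),
        low_confidence=low_confidence,
    )


def average_real_variability(
    w: WindowedRecording, window: str, channel: str, weighted: bool = True
) -> float:
    """Average real variability of a window.

    Successive-pair differences are taken within the window only: for the
    day or night ARV no pair spans the day/night boundary (night readings
    recorded before the first waking form their own run).  The default
    weights each absolute difference by the time elapsed between the two
    readings; the unweighted variant is the plain mean absolute successive
    difference.
    """
    idx = w.window_indices(window)
    values = w.recording.channel(channel)
    valid = w.recording.valid_mask() & ~np.isnan(values)
    ts = w.recording.timestamps().astype("datetime64[s]").astype(float)

    if window == "24h":
        runs = [[k for k in idx if valid[k]]]
    else:
        # split the window's valid readings into time-contiguous runs: a run
        # breaks where a reading from the other window falls in between
        other = set(w.window_indices("night" if window == "day" else "day"))
        runs = []
        current: list[int] = []
        prev = None
        for k in sorted(idx):
            if prev is not None and any(m in other for m in range(prev + 1, k)):
                if current:
                    runs.append(current)
                current = []
            if valid[k]:
                current.append(k)
            prev = k
        if current:
            runs.append(current)

    diffs, weights = [], []
    for run in runs:
        for a, b in zip(run[:-1], run[1:]):
            diffs.append(abs(values[b] - values[a]))
            weights.append((ts[b] - ts[a]) / 3600.0)
    if not diffs:
        raise ValueError(
            f"fewer than 2 valid {channel} readings in {window} window; ARV undefined"
        )
    diffs_arr = np.asarray(diffs)
    if weighted:
        wts = np.asarray(weights)
        return float((wts * diffs_arr).sum() / wts.sum())
    return float(diffs_arr.mean())


def nocturnal_dip(w: WindowedRecording) -> float:
    """Percentage fall of the night-time SBP mean relative to the daytime mean."""
    day = window_mean(w, "day", "sbp")
    night = window_mean(w, "night", "sbp")
    return 100.0 * (day - night) / day


def compute_metrics(
    rec: ABPMRecording,
    schedule: Schedule | None = None,
    trough_rule: str = "lowest2",
    arv_weighted: bool = True,
) -> MetricsRow:
    """All derived scalars for one recording.

    QC status is recorded either way: recordings failing the screening rules
    still yield a full row, flagged ``qc_passed=False``, so the caller decides
    whether to discard them.
    """
    w = segment_windows(rec)
    qc = qc_validity(rec, schedule)
    mbps = morning_surge(w, trough_rule=trough_rule)
    night_sbp, _ = _window_values(w, "night", "sbp")
    arv = {
        (win, ch): average_real_variability(w, win, ch, weighted=arv_weighted)
        for win in ("24h", "day", "night")
        for ch in ("sbp", "dbp")
    }
    return MetricsRow(
        subject_id=rec.subject_id,
        timepoint=rec.timepoint,
        mean_24h_sbp=window_mean(w, "24h", "sbp"),
        mean_24h_dbp=window_mean(w, "24h", "dbp"),
        mean_day_sbp=window_mean(w, "day", "sbp"),
        mean_day_dbp=window_mean(w, "day", "dbp"),
        mean_night_sbp=window_mean(w, "night", "sbp"),
        mean_night_dbp=window_mean(w, "night", "dbp"),
        arv_24h_sbp=arv[("24h", "sbp")],
        arv_day_sbp=arv[("day", "sbp")],
        arv_night_sbp=arv[("night", "sbp")],
        arv_24h_dbp=arv[("24h", "dbp")],
        arv_day_dbp=arv[("day", "dbp")],
        arv_night_dbp=arv[("night", "dbp")],
        mbps=mbps.surge,
        morning_sbp=mbps.morning_mean,
        lowest_night_sbp=float(night_sbp.min()),
        dip_pct=nocturnal_dip(w),
        qc_passed=qc.passed,
    )


def metrics_table(
    recordings: Sequence[ABPMRecording],
    schedule: Schedule | None = None,
    trough_rule: str = "lowest2",
    arv_weighted: bool = True,
) -> pd.DataFrame:
    """One MetricsRow per recording, as a DataFrame."""
    rows = [
        compute_metrics(
            rec, schedule=schedule, trough_rule=trough_rule, arv_weighted=arv_weighted
        ).to_dict()
        for rec in recordings
    ]
    return pd.DataFrame(rows)
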