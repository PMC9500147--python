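"""Shared fixtures: hand-built recordings and an independent split-plot oracle."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest
from scipy import stats

from abpsurge.model import ABPMRecording, BPReading, SleepDiary

WAKE = datetime(2022, 1, 10, 7, 0)
BED = datetime(2022, 1, 10, 23, 0)


def reading(minutes_after_wake: float, sbp: float, dbp: float = 70.0,
            hr: float | None = 65.0, valid: bool = True) -> BPReading:
    return BPReading(
        timestamp=WAKE + timedelta(minutes=minutes_after_wake),
        sbp=sbp, dbp=dbp, hr=hr, valid=valid,
    )


def make_recording(readings, subject_id="S01", timepoint="baseline",
                   wake=WAKE, bed=BED) -> ABPMRecording:
    return ABPMRecording(
        subject_id=subject_id, timepoint=timepoint, readings=list(readings),
        diary=SleepDiary(wake_time=wake, bed_time=bed),
    )


@pytest.fixture
def nominal_recording():
    """Complete nominal recording: 32 daytime half-hourly + 8 hourly night
    readings, constant 120/70."""
    rs = [reading(m, 120.0) for m in range(0, 16 * 60, 30)]
    rs += [reading(m, 120.0) for m in range(16 * 60, 24 * 60, 60)]
    return make_recording(rs)


def split_plot_oracle(data: np.ndarray) -> dict:
    """Independent split-plot ANOVA via direct sums-of-squares projection.

    ``data`` has shape (G groups, n subjects, T times), balanced.  Returns F
    and p for the group, time and interaction effects with their error
    strata (group vs subjects-within-groups; time and interaction vs the
    within-subject residual).
    """
    g_n, n, t_n = data.shape
    mu = data.mean()
    subj = data.mean(axis=2)          # (G, n)
    grp = data.mean(axis=(1, 2))      # (G,)
    tim = data.mean(axis=(0, 1))      # (T,)
    cell = data.mean(axis=1)          # (G, T)

    ss_between_subj = t_n * ((subj - mu) ** 2).sum()
    ss_group = n * t_n * ((grp - mu) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_time = g_n * n * ((tim - mu) ** 2).sum()
    ss_cells = n * ((cell - mu) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_time
    ss_total = ((data - mu) ** 2).sum()
    ss_resid = ss_total - ss_between_subj - ss_time - ss_inter

    df_group, df_sw = g_n - 1, g_n * (n - 1)
    df_time, df_int = t_n - 1, (g_n - 1) * (t_n - 1)
    df_resid = (t_n - 1) * g_n * (n - 1)
    f_group = (ss_group / df_group) / (ss_subj_within / df_sw)
    f_time = (ss_time / df_time) / (ss_resid / df_resid)
    f_int = (ss_inter / df_int) / (ss_resid / df_resid)
    return {
        "F_group": f_group, "p_group": stats.f.sf(f_group, df_group, df_sw),
        "F_time": f_time, "p_time": stats.f.sf(f_time, df_time, df_resid),
        "F_interaction": f_int,
        "p_interaction": stats.f.sf(f_int, df_int, df_resid),
    }


def anova_fixture_data(seed=42, g_n=2, n=4, t_n=3, effect=-8.0):
    """Balanced 2x4x3 dataset with a programmed group x time effect."""
    rng = np.random.default_rng(seed)
    data = 120.0 + 5.0 * rng.standard_normal((g_n, n, 1)) + np.zeros((g_n, n, t_n))
    data += 2.0 * rng.standard_normal((g_n, n, t_n))
    data[0, :, 1] += effect          # group 0 shifted at mid
    data[0, :, 2] += effect / 2.0
    return data


def long_table_from_array(data: np.ndarray, metric="mean_24h_sbp"):
    """Long cohort table from a (G, n, T) array."""
    import pandas as pd

    from abpsurge.model import TIMEPOINTS

    rows = []
    for g in range(data.shape[0]):
        for i in range(data.shape[1]):
            for t, tp in enumerate(TIMEPOINTS[: data.shape[2]]):
                rows.append(
                    {
                        "subject_id": f"G{g}S{i:02d}",
                        "group": f"G{g}",
                        "timepoint": tp,
                        "metric": metric,
                        "value": float(data[g, i, t]),
                    }
                )
    return pd.DataFrame(rows)
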