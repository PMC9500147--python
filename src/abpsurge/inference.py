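"""Group-level statistics for a 2-group x 3-timepoint mixed (split-plot) design.

The cohort table is a long-format DataFrame with columns
``subject_id, group, timepoint, metric, value`` — one row per subject-visit
per derived measure.  The analysis mirrors the standard workflow of
exercise-training ABPM trials: a two-way repeated-measures (split-plot)
ANOVA per measure, Bonferroni-adjusted paired and between-group post hocs,
day-to-day reliability (ICC and within-subject CV%), and an a priori
two-sample sample-size calculation on Cohen's d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import TIMEPOINTS

__all__ = [
    "AnovaResult",
    "Comparison",
    "ReliabilityResult",
    "SampleSizeResult",
    "validate_cohort_table",
    "mixed_anova",
    "bonferroni_posthoc",
    "icc_day_to_day",
    "sample_size_two_group",
]

COHORT_COLUMNS = ("subject_id", "group", "timepoint", "metric", "value")


@dataclass(frozen=True)
class AnovaResult:
    F_group: float
    F_time: float
    F_interaction: float
    df_group: tuple[int, int]
    df_time: tuple[int, int]
    df_interaction: tuple[int, int]
    p_group: float
    p_time: float
    p_interaction: float
    cell_means: pd.DataFrame
    gg_epsilon: float | None = None
    p_time_gg: float | None = None


@dataclass(frozen=True)
class Comparison:
    """One post hoc contrast.

    Sign convention: within-group contrasts are later minus earlier
    timepoint; between-group contrasts are first group minus second.
    """

    scope: str          # "within" | "between"
    group: str | None   # within-group family
    timepoint: str | None  # between-group family
    pair: tuple[str, str]
    estimate: float
    t: float
    df: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    cv_pct: float
    n: int


@dataclass(frozen=True)
class SampleSizeResult:
    n_per_group: int
    n_total: int
    achieved_power: float
    n_recruit: int


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject_id", "timepoint", "metric"])
    if dup.any():
        raise ValueError("duplicate (subject, timepoint, metric) rows in cohort table")
    multi = table.groupby("subject_id")["group"].nunique()
    if (multi > 1).any():
        bad = multi[multi > 1].index.tolist()
        raise ValueError(f"subjects assigned to more than one group: {bad}")
    return table


def _complete_wide(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Subject x timepoint matrix for one metric; errors on missing cells."""
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in cohort table")
    wide = sub.pivot(index="subject_id", columns="timepoint", values="value")
    missing_tp = [tp for tp in TIMEPOINTS if tp not in wide.columns]
    if missing_tp or wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist() if not missing_tp else []
        raise ValueError(
            f"incomplete data for metric {metric!r} "
            f"(missing timepoints {missing_tp}, incomplete subjects {bad}); "
            f"apply listwise deletion upstream"
        )
    return wide[list(TIMEPOINTS)]


def mixed_anova(table: pd.DataFrame, metric: str) -> AnovaResult:
    """Split-plot ANOVA: between-subjects group, within-subjects timepoint.

    Classical decomposition with separate error strata — group is tested
    against subjects-within-groups, time and group x time against the
    within-subject residual.  Requires complete data (every subject measured
    at all timepoints) and at least two subjects per group.  With three
    within-subject levels the Greenhouse-Geisser epsilon is reported
    alongside, but inference defaults to the uncorrected F.
    """
    validate_cohort_table(table)
    sub = table[table["metric"] == metric]
    wide = _complete_wide(table, metric)
    groups = sub.drop_duplicates("subject_id").set_index("subject_id")["group"]
    counts = groups.loc[wide.index].value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"need >= 2 complete subjects per group, got {counts.to_dict()}"
        )

    import pingouin as pg

    data = sub[["subject_id", "group", "timepoint", "value"]]
    cell_means = (
        data.groupby(["group", "timepoint"], observed=True)["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    if len(counts) == 1:
        # degenerate split plot: no between-subjects factor, the design
        # collapses to a one-way repeated-measures ANOVA on time
        n = wide.shape[0]
        aov1 = pg.rm_anova(
            data=data, dv="value", within="timepoint", subject="subject_id"
        ).iloc[0]
        return AnovaResult(
            F_group=float("nan"), F_time=float(aov1["F"]),
            F_interaction=float("nan"),
            df_group=(0, n - 1),
            df_time=(int(aov1["ddof1"]), int(aov1["ddof2"])),
            df_interaction=(0, int(aov1["ddof2"])),
            p_group=float("nan"), p_time=float(aov1["p_unc"]),
            p_interaction=float("nan"),
            cell_means=cell_means,
            gg_epsilon=float(aov1["eps"]) if "eps" in aov1 else None,
        )
    if np.isclose(data["value"].var(ddof=0), 0.0):
        # degenerate: no variation anywhere, define all F = 0
        zero = (0.0, 1.0)
        n = wide.shape[0]
        g = len(counts)
        return AnovaResult(
            F_group=zero[0], F_time=zero[0], F_interaction=zero[0],
            df_group=(g - 1, n - g),
            df_time=(2, 2 * (n - g)),
            df_interaction=(2 * (g - 1), 2 * (n - g)),
            p_group=zero[1], p_time=zero[1], p_interaction=zero[1],
            cell_means=cell_means,
        )
    aov = pg.mixed_anova(
        data=data, dv="value", within="timepoint", subject="subject_id",
        between="group", correction=True,
    ).set_index("Source")
    row_g, row_t, row_i = aov.loc["group"], aov.loc["timepoint"], aov.loc["Interaction"]

    def _f(row) -> float:
        return 0.0 if np.isnan(row["F"]) and row["SS"] == 0 else float(row["F"])

    def _p(row) -> float:
        return 1.0 if np.isnan(row["p_unc"]) and row["SS"] == 0 else float(row["p_unc"])

    return AnovaResult(
        F_group=_f(row_g), F_time=_f(row_t), F_interaction=_f(row_i),
        df_group=(int(row_g["DF1"]), int(row_g["DF2"])),
        df_time=(int(row_t["DF1"]), int(row_t["DF2"])),
        df_interaction=(int(row_i["DF1"]), int(row_i["DF2"])),
        p_group=_p(row_g), p_time=_p(row_t), p_interaction=_p(row_i),
        cell_means=cell_means,
        gg_epsilon=float(row_t["eps"]) if "eps" in aov.columns else None,
        p_time_gg=float(row_t["p_GG_corr"]) if "p_GG_corr" in aov.columns else None,
    )


def bonferroni_posthoc(table: pd.DataFrame, metric: str) -> list[Comparison]:
    """Bonferroni-adjusted post hoc contrasts for one metric.

    Within each group, paired t tests over the three timepoint pairs
    (family size m = 3 per group); between groups, two-sample t tests at
    each timepoint (m = 3).  Adjusted p values are capped at 1.0.
    """
    validate_cohort_table(table)
    wide = _complete_wide(table, metric)
    sub = table[table["metric"] == metric]
    groups = sub.drop_duplicates("subject_id").set_index("subject_id")["group"]
    group_labels = list(dict.fromkeys(groups.loc[wide.index]))

    out: list[Comparison] = []
    time_pairs = list(combinations(TIMEPOINTS, 2))
    m_within = len(time_pairs)
    for g in group_labels:
        block = wide.loc[groups.loc[wide.index] == g]
        for earlier, later in time_pairs:
            d = block[later] - block[earlier]
            if np.isclose(d.var(ddof=1), 0.0):
                if np.isclose(d.mean(), 0.0):
                    t_stat, p = 0.0, 1.0
                else:
                    raise ValueError(
                        f"zero variance in paired differences {earlier}->{later} "
                        f"for group {g}; p undefined"
                    )
            else:
                t_stat, p = stats.ttest_rel(block[later], block[earlier])
            out.append(
                Comparison(
                    scope="within", group=g, timepoint=None,
                    pair=(earlier, later),
                    estimate=float(d.mean()), t=float(t_stat),
                    df=float(len(d) - 1),
                    p_raw=float(p), p_adjusted=min(1.0, m_within * float(p)),
                )
            )
    if len(group_labels) == 2:
        g1, g2 = group_labels
        m_between = len(TIMEPOINTS)
        for tp in TIMEPOINTS:
            a = wide.loc[groups.loc[wide.index] == g1, tp]
            b = wide.loc[groups.loc[wide.index] == g2, tp]
            if np.isclose(pd.concat([a, b]).var(ddof=1), 0.0):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(a, b)
            out.append(
                Comparison(
                    scope="between", group=None, timepoint=tp,
                    pair=(g1, g2),
                    estimate=float(a.mean() - b.mean()), t=float(t_stat),
                    df=float(len(a) + len(b) - 2),
                    p_raw=float(p), p_adjusted=min(1.0, m_between * float(p)),
                )
            )
    return out


def icc_day_to_day(
    day1: Sequence[float], day2: Sequence[float]
) -> ReliabilityResult:
    """Day-to-day reliability of a repeated ambulatory measure.

    ICC is the two-way random-effects, absolute-agreement, single-measurement
    form (ICC(2,1)) computed from the subjects x days mean squares.  CV% is
    the within-subject standard deviation — sqrt(sum d_i^2 / 2n) over paired
    differences — expressed as a percentage of the grand mean.
    """
    x = np.asarray(day1, dtype=float)
    y = np.asarray(day2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("day1 and day2 must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 subjects with both days, got {n}")
    d = x - y
    grand = float(np.concatenate([x, y]).mean())
    sd_w = math.sqrt(float((d**2).sum()) / (2 * n))
    cv_pct = 100.0 * sd_w / grand

    if np.allclose(d, 0.0) and np.std(x) > 0:
        icc = 1.0
    else:
        import pingouin as pg

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "day": ["day1", "day2"] * n,
                "value": np.column_stack([x, y]).ravel(),
            }
        )
        tab = pg.intraclass_corr(
            data=long, targets="subject", raters="day", ratings="value"
        ).set_index("Type")
        icc = float(tab.loc["ICC(A,1)", "ICC"])  # two-way random, absolute, single
    return ReliabilityResult(icc=icc, cv_pct=cv_pct, n=n)


def _power_two_sample(n: int, d: float, alpha: float) -> float:
    """Power of the two-sided two-sample t test at n per group."""
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    crit = stats.t.ppf(1 - alpha / 2.0, df)
    return float(1 - stats.nct.cdf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def sample_size_two_group(
    d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    attrition: float = 0.0,
) -> SampleSizeResult:
    """Smallest per-group n achieving the requested power.

    Uses the exact noncentral-t power of a two-sided two-sample t test with
    noncentrality ``d * sqrt(n/2)`` and ``2n - 2`` degrees of freedom,
    searching upward from the minimum df-valid size (n = 2).  The recruitment
    target inflates the total for the anticipated attrition proportion.
    """
    if not d > 0:
        raise ValueError("effect size d must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie strictly between 0 and 1")
    if not 0 <= attrition < 1:
        raise ValueError("attrition must lie in [0, 1)")
    n = 2
    while _power_two_sample(n, d, alpha) < power:
        n += 1
        if n > 10_000_000:  # pragma: no cover
            raise RuntimeError("sample-size search failed to converge")
    achieved = _power_two_sample(n, d, alpha)
    n_total = 2 * n
    return SampleSizeResult(
        n_per_group=n,
        n_total=n_total,
        achieved_power=achieved,
        n_recruit=math.ceil(n_total / (1.0 - attrition)),
    )
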