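"""Seed-replicated recovery of the programmed training effects.

The study-calibrated generator programs group-mean changes in the training
arm (24-h SBP, night-time SBP, MBPS and 24-h SBP ARV at the post-training
and post-detraining visits).  This module re-estimates those changes by
running the full pipeline — simulate, QC, metrics, paired contrasts — on
many replicate cohorts, which is how both the acceptance checks and the
effect-recovery analysis quantify estimator bias and Monte-Carlo spread.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .inference import bonferroni_posthoc
from .metrics import metrics_table
from .pipeline import cohort_long_table
from .simulate import default_config, simulate_cohort

__all__ = ["child_seeds", "recover_training_effects", "summarize_recovery"]

RECOVERY_COLUMNS = (
    "d24_mid", "d24_end", "dnight_mid", "p_night_mid_adj",
    "dmbps_mid", "darv24_mid",
)


def child_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic replicate seeds (< 2**31) derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31)


def recover_training_effects(
    n_seeds: int = 200,
    base_seed: int = 0,
    group: str = "TG-DT",
    n_subjects: int = 13,
) -> pd.DataFrame:
    """One row per replicate cohort of the training arm.

    Columns: group-mean (mid - baseline) changes in 24-h SBP, night-time SBP,
    MBPS and 24-h SBP ARV; the (end - baseline) 24-h SBP change; and the
    Bonferroni-adjusted within-group p value of the baseline-vs-mid
    night-time contrast.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in child_seeds(base_seed, n_seeds):
            cfg = default_config(seed=int(seed), n_per_group={group: n_subjects})
            recordings, design, _ = simulate_cohort(cfg)
            mdf = metrics_table(recordings)
            mdf = mdf[mdf["qc_passed"]]
            piv = mdf.pivot(index="subject_id", columns="timepoint")

            def change(col: str, tp: str) -> float:
                return float((piv[(col, tp)] - piv[(col, "baseline")]).mean())

            long = cohort_long_table(mdf, design, metrics=("mean_night_sbp",))
            night = [
                c for c in bonferroni_posthoc(long, "mean_night_sbp")
                if c.scope == "within" and c.pair == ("baseline", "mid")
            ][0]
            rows.append(
                {
                    "seed": int(seed),
                    "d24_mid": change("mean_24h_sbp", "mid"),
                    "d24_end": change("mean_24h_sbp", "end"),
                    "dnight_mid": change("mean_night_sbp", "mid"),
                    "p_night_mid_adj": night.p_adjusted,
                    "dmbps_mid": change("mbps", "mid"),
                    "darv24_mid": change("arv_24h_sbp", "mid"),
                }
            )
    return pd.DataFrame(rows)


def summarize_recovery(df: pd.DataFrame) -> pd.DataFrame:
    """Across-seed mean, SEM and median for each recovery column."""
    cols = [c for c in RECOVERY_COLUMNS if c in df.columns]
    out = pd.DataFrame(
        {
            "mean": df[cols].mean(),
            "sem": df[cols].std(ddof=1) / np.sqrt(len(df)),
            "median": df[cols].median(),
        }
    )
    out.index.name = "quantity"
    return out
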