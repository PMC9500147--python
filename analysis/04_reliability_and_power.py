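#!/usr/bin/env python
"""Day-to-day reliability of the ambulatory measures, and the a priori
sample-size calculation.

Reliability: simulates two replicate baseline monitoring days for every
subject (no training effects anywhere), then computes the two-way
random-effects ICC(2,1) and the within-subject CV% for 24-h, daytime and
night-time SBP.  Sample size: the noncentral-t search for a two-sided
two-sample t test at the effect sizes used to plan training trials of this
kind, with a 20% attrition allowance.

Also demonstrates resting-BP selection: the lowest of three seated readings
per channel, with MAP recomputed from the selected pressures.
"""

from __future__ import annotations

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from abpsurge.inference import icc_day_to_day, sample_size_two_group
from abpsurge.metrics import metrics_table, resting_bp
from abpsurge.model import BPReading
from abpsurge.simulate import EffectShift, default_config, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def reliability(seed: int) -> pd.DataFrame:
    # two replicate baseline days: reuse the first two visits with all
    # training effects removed, so differences are purely day-to-day
    cfg = default_config(seed=seed, n_per_group={"TG-DT": 13, "CON": 12})
    cfg.effects = {k: EffectShift() for k in cfg.effects}
    cfg.timepoints = ("baseline", "mid")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recordings, _, _ = simulate_cohort(cfg)
        mdf = metrics_table(recordings)
    rows = []
    for metric in ("mean_24h_sbp", "mean_day_sbp", "mean_night_sbp"):
        piv = mdf.pivot(index="subject_id", columns="timepoint", values=metric)
        rel = icc_day_to_day(piv["baseline"], piv["mid"])
        rows.append({"metric": metric, "icc": round(rel.icc, 3),
                     "cv_pct": round(rel.cv_pct, 2), "n": rel.n})
    return pd.DataFrame(rows)


def resting_demo(seed: int) -> None:
    rng = np.random.default_rng(seed)
    from datetime import datetime, timedelta

    t0 = datetime(2022, 1, 10, 9, 0)
    selected = []
    for _ in range(25):
        base_s = rng.normal(126.0, 5.0)
        base_d = rng.normal(72.0, 6.0)
        triplet = [
            BPReading(
                timestamp=t0 + timedelta(minutes=k),
                sbp=base_s + rng.normal(0, 3.0),
                dbp=base_d + rng.normal(0, 3.0),
                hr=rng.normal(68, 8),
            )
            for k in range(3)
        ]
        selected.append(resting_bp(triplet))
    sbp = np.mean([r.sbp for r in selected])
    dbp = np.mean([r.dbp for r in selected])
    mp = np.mean([r.map for r in selected])
    print(f"resting selection over 25 triplets: SBP {sbp:.0f} / DBP {dbp:.0f} "
          f"mmHg, MAP {mp:.0f} mmHg")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "reliability.csv")
    args = parser.parse_args()

    rel = reliability(args.seed)
    print("day-to-day reliability of simulated baseline measures:")
    print(rel.to_string(index=False))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    rel.to_csv(args.out, index=False)

    print("\nsample size (two-sided two-sample t, alpha 0.05, power 0.80):")
    for d in (1.33, 1.38, 1.40):
        res = sample_size_two_group(d=d, attrition=0.20)
        print(f"  d = {d:4.2f}: n/group {res.n_per_group}, total {res.n_total}, "
              f"power {res.achieved_power:.3f}, recruit {res.n_recruit}")

    print()
    resting_demo(args.seed)
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
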