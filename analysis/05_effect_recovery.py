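#!/usr/bin/env python
"""Seed-replicated recovery of the programmed training effects.

Re-estimates the generator's programmed group-mean changes (24-h SBP, MBPS,
night-time SBP and 24-h SBP ARV after training; 24-h SBP after detraining)
by running the full pipeline on 200 replicate training-arm cohorts (n = 13),
and compares the across-seed means with the programmed values.  Writes
results/recovery.csv (per-seed) and results/recovery_summary.csv.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from abpsurge.recovery import recover_training_effects, summarize_recovery

ROOT = Path(__file__).resolve().parents[1]

PROGRAMMED = {
    "d24_mid": -8.0,
    "d24_end": -6.0,
    "dnight_mid": -1.0,
    "dmbps_mid": -6.0,
    "darv24_mid": -2.16,
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-seeds", type=int, default=200)
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    df = recover_training_effects(n_seeds=args.n_seeds, base_seed=args.seed)
    summary = summarize_recovery(df)
    summary["programmed"] = pd.Series(PROGRAMMED)
    summary["bias"] = summary["mean"] - summary["programmed"]
    summary["within_3_sem"] = (summary["bias"].abs() <= 3 * summary["sem"]).where(
        summary["programmed"].notna()
    )

    print(f"{args.n_seeds} replicate cohorts (training arm, n = 13):")
    print(summary.round(3).to_string())
    frac_ns = (df["p_night_mid_adj"] > 0.05).mean()
    print(f"\nnight-time contrast non-significant in {100 * frac_ns:.0f}% of "
          f"replicates (median adjusted p = {df['p_night_mid_adj'].median():.3f})")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out_dir / "recovery.csv", index=False)
    summary.to_csv(args.out_dir / "recovery_summary.csv")
    print(f"\nwrote {args.out_dir / 'recovery.csv'} and recovery_summary.csv")


if __name__ == "__main__":
    main()
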