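#!/usr/bin/env python
"""QC-screen the simulated cohort and derive per-recording statistics.

Loads the raw tables written by 01_simulate_cohort.py, applies the ABPM
screening rules (>= 80% valid readings, no missing hour), computes window
means, morning surge, ARV and nocturnal dip per recording, and writes
results/metrics.csv.  Prints a baseline group summary in the usual
cohort-table layout.
"""

from __future__ import annotations

import argparse
import warnings
from pathlib import Path

import pandas as pd

from abpsurge.metrics import metrics_table
from abpsurge.model import load_recordings

ROOT = Path(__file__).resolve().parents[1]

SUMMARY_COLS = (
    "mean_24h_sbp", "mean_day_sbp", "mean_night_sbp",
    "morning_sbp", "lowest_night_sbp", "mbps",
    "arv_24h_sbp", "arv_day_sbp", "arv_night_sbp", "dip_pct",
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort-dir", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "metrics.csv")
    args = parser.parse_args()

    recordings = load_recordings(
        args.cohort_dir / "readings.csv", args.cohort_dir / "diary.csv"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mdf = metrics_table(recordings)
    n_pass = int(mdf["qc_passed"].sum())
    print(f"{len(mdf)} recordings; {n_pass} passed QC, {len(mdf) - n_pass} discarded")

    design = pd.read_csv(args.cohort_dir / "design.csv", dtype={"subject_id": str})
    base = (
        mdf[mdf.timepoint == "baseline"]
        .merge(design, on="subject_id")
        .groupby("group")[list(SUMMARY_COLS)]
    )
    summary = base.mean().round(1).T
    summary.columns = [f"{c} mean" for c in summary.columns]
    sds = base.std().round(1).T
    for g in sds.columns:
        summary[f"{g} SD"] = sds[g]
    print("\nbaseline group summary (mmHg; dip in %):")
    print(summary.to_string())

    args.out.parent.mkdir(parents=True, exist_ok=True)
    mdf.to_csv(args.out, index=False)
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
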