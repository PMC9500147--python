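"""End-to-end orchestration: simulate -> QC -> metrics -> inference -> report.

Every stage boundary is file-expressible: the pipeline writes the readings,
diary, design, truth, metrics and cohort tables as CSV, so each intermediate
can be regenerated and diffed independently.  The report mirrors the
group x timepoint presentation of training-trial papers: per-metric cell
means +- SD, the split-plot ANOVA table, and Bonferroni-adjusted within- and
between-group contrasts with significance marks at alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import pandas as pd

from . import __version__
from .inference import bonferroni_posthoc, mixed_anova, validate_cohort_table
from .metrics import metrics_table
from .model import write_recordings
from .simulate import default_config, simulate_cohort

__all__ = [
    "RunConfig",
    "RunManifest",
    "DEFAULT_METRICS",
    "load_run_config",
    "cohort_long_table",
    "analyze_cohort",
    "render_report_markdown",
    "run_pipeline",
]

logger = logging.getLogger("abpsurge")

DEFAULT_METRICS = (
    "mean_24h_sbp", "mean_day_sbp", "mean_night_sbp",
    "mean_24h_dbp", "mean_day_dbp", "mean_night_dbp",
    "mbps", "arv_24h_sbp", "arv_day_sbp", "arv_night_sbp", "dip_pct",
)


@dataclass
class RunConfig:
    """User-facing pipeline configuration (JSON-serialisable)."""

    seed: int = 0
    n_per_group: dict = field(default_factory=lambda: {"TG-DT": 13, "CON": 12})
    missingness: float = 0.0
    trough_rule: str = "lowest2"
    arv_weighted: bool = True
    alpha: float = 0.05
    metrics: tuple = DEFAULT_METRICS


def load_run_config(source: dict | str | Path) -> RunConfig:
    """Validate a config mapping or JSON file into a :class:`RunConfig`."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = json.load(fh)
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(source) - allowed
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    cfg = RunConfig(**source)
    if not isinstance(cfg.seed, int):
        raise ValueError("config field 'seed' must be an integer")
    if not 0.0 <= cfg.missingness < 1.0:
        raise ValueError("config field 'missingness' must lie in [0, 1)")
    if not 0.0 < cfg.alpha < 1.0:
        raise ValueError("config field 'alpha' must lie in (0, 1)")
    cfg.metrics = tuple(cfg.metrics)
    return cfg


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    paths: dict
    created: str
    qc_summary: dict


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cohort_long_table(
    metrics_df: pd.DataFrame, design: pd.DataFrame, metrics: tuple = DEFAULT_METRICS
) -> pd.DataFrame:
    """Melt a metrics table into the long (subject, group, timepoint, metric,
    value) cohort format, joining group labels from the design table."""
    merged = metrics_df.merge(design, on="subject_id", how="left")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "subject_id"].unique().tolist()
        raise ValueError(f"subjects absent from design table: {missing}")
    long = merged.melt(
        id_vars=["subject_id", "group", "timepoint"],
        value_vars=[m for m in metrics if m in merged.columns],
        var_name="metric",
        value_name="value",
    )
    return validate_cohort_table(long)


def _listwise_complete(long: pd.DataFrame, timepoints: tuple) -> tuple[pd.DataFrame, list]:
    counts = long.groupby("subject_id")["timepoint"].nunique()
    dropped = counts[counts < len(timepoints)].index.tolist()
    return long[~long["subject_id"].isin(dropped)], dropped


def analyze_cohort(
    metrics_df: pd.DataFrame,
    design: pd.DataFrame,
    metrics: tuple = DEFAULT_METRICS,
    alpha: float = 0.05,
) -> dict:
    """QC-filter, listwise-delete, and run ANOVA + post hocs per metric."""
    n_in = len(metrics_df)
    kept = metrics_df[metrics_df["qc_passed"]] if "qc_passed" in metrics_df else metrics_df
    n_qc = len(kept)
    logger.info("QC filter: %d of %d recordings retained", n_qc, n_in)
    long = cohort_long_table(kept, design, metrics)
    timepoints = tuple(sorted(long["timepoint"].unique(),
                              key=["baseline", "mid", "end"].index))
    long, dropped = _listwise_complete(long, timepoints)
    if dropped:
        logger.info("listwise deletion removed %d incomplete subjects: %s",
                    len(dropped), dropped)
    present = design.merge(long[["subject_id"]].drop_duplicates(), on="subject_id")
    for g, n in design.groupby("group").size().items():
        if (present["group"] == g).sum() == 0:
            raise RuntimeError(f"QC removed every subject of group {g!r}; aborting")

    report: dict = {
        "qc": {"recordings_in": n_in, "recordings_passed": n_qc,
               "subjects_dropped_listwise": dropped},
        "alpha": alpha,
        "metrics": {},
    }
    for metric in metrics:
        if metric not in set(long["metric"]):
            continue
        aov = mixed_anova(long, metric)
        posthoc = bonferroni_posthoc(long, metric)
        report["metrics"][metric] = {
            "anova": {
                "F_group": aov.F_group, "p_group": aov.p_group,
                "df_group": list(aov.df_group),
                "F_time": aov.F_time, "p_time": aov.p_time,
                "df_time": list(aov.df_time),
                "F_interaction": aov.F_interaction,
                "p_interaction": aov.p_interaction,
                "df_interaction": list(aov.df_interaction),
                "gg_epsilon": aov.gg_epsilon,
            },
            "cell_means": aov.cell_means.to_dict(orient="records"),
            "posthoc": [
                {
                    "scope": c.scope, "group": c.group, "timepoint": c.timepoint,
                    "pair": list(c.pair), "estimate": c.estimate, "t": c.t,
                    "df": c.df, "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
                    "significant": bool(c.p_adjusted <= alpha),
                }
                for c in posthoc
            ],
        }
    return report


def render_report_markdown(report: dict) -> str:
    """Human-readable summary of an analysis report."""
    lines = ["# Ambulatory BP analysis report", ""]
    qc = report["qc"]
    lines += [
        f"QC: {qc['recordings_passed']}/{qc['recordings_in']} recordings retained; "
        f"{len(qc['subjects_dropped_listwise'])} subjects listwise-deleted.",
        "",
    ]
    for metric, block in report["metrics"].items():
        lines += [f"## {metric}", "", "| group | timepoint | mean | SD | n |",
                  "|---|---|---|---|---|"]
        for row in block["cell_means"]:
            lines.append(
                f"| {row['group']} | {row['timepoint']} | {row['mean']:.1f} "
                f"| {row['std']:.1f} | {row['count']} |"
            )
        a = block["anova"]
        lines += [
            "",
            f"ANOVA: group F({a['df_group'][0]},{a['df_group'][1]}) = "
            f"{a['F_group']:.2f}, p = {a['p_group']:.3f}; "
            f"time F({a['df_time'][0]},{a['df_time'][1]}) = "
            f"{a['F_time']:.2f}, p = {a['p_time']:.3f}; "
            f"interaction F = {a['F_interaction']:.2f}, "
            f"p = {a['p_interaction']:.3f}",
            "",
            "| contrast | estimate | t | p (Bonferroni) | |",
            "|---|---|---|---|---|",
        ]
        for c in block["posthoc"]:
            label = (
                f"{c['group']}: {c['pair'][1]} - {c['pair'][0]}"
                if c["scope"] == "within"
                else f"{c['pair'][0]} - {c['pair'][1]} at {c['timepoint']}"
            )
            mark = "*" if c["significant"] else ""
            lines.append(
                f"| {label} | {c['estimate']:.2f} | {c['t']:.2f} "
                f"| {c['p_adjusted']:.3f} | {mark} |"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: dict | str | Path | RunConfig, out_dir: str | Path) -> dict:
    """Execute the full chain and write all stage outputs under ``out_dir``.

    Returns the path map.  Outputs are deterministic given the config seed
    (the manifest carries a wall-clock timestamp and is written separately).
    """
    cfg = config if isinstance(config, RunConfig) else load_run_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg = default_config(
        seed=cfg.seed, n_per_group=dict(cfg.n_per_group), missingness=cfg.missingness
    )
    recordings, design, truth = simulate_cohort(sim_cfg)
    logger.info("simulated %d recordings (%d subjects)", len(recordings), len(design))
    paths = {name: out / f"{name}.csv"
             for name in ("readings", "diary", "design", "truth", "metrics", "cohort")}
    write_recordings(recordings, paths["readings"], paths["diary"])
    design.to_csv(paths["design"], index=False)
    truth.to_csv(paths["truth"], index=False)

    mdf = metrics_table(
        recordings, trough_rule=cfg.trough_rule, arv_weighted=cfg.arv_weighted
    )
    mdf.to_csv(paths["metrics"], index=False)
    report = analyze_cohort(mdf, design, metrics=cfg.metrics, alpha=cfg.alpha)
    kept = mdf[mdf["qc_passed"]]
    cohort_long_table(kept, design, cfg.metrics).to_csv(paths["cohort"], index=False)

    paths["report_json"] = out / "report.json"
    paths["report_md"] = out / "report.md"
    with open(paths["report_json"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["report_md"].write_text(render_report_markdown(report))

    manifest = RunManifest(
        version=__version__,
        config_hash=_config_hash(cfg),
        seed=cfg.seed,
        paths={k: str(v) for k, v in paths.items()},
        created=datetime.now().isoformat(timespec="seconds"),
        qc_summary=report["qc"],
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
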