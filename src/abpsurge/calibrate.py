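"""Calibration of the synthetic cohort to the reference study conditions.

The generator's defaults emulate the trial the package models: a
training-detraining arm (n = 13) and a control arm (n = 12), measured at
baseline, after 8 weeks of isometric resistance training (mid) and after 8
weeks of detraining (end).  Calibration works in two stages:

* **Linear stage (exact).**  Window means of the noise-free profile are
  linear in the day level, night level and surge amplitude, with weights
  given by the schedule averages of the shape functions.  The baseline day
  and night levels, and the day/night shifts that realise a programmed
  change in the 24-h and night-time means, are therefore obtained by solving
  small linear systems — no simulation involved.

* **Monte-Carlo stage (frozen).**  The morning surge involves the sampled
  nocturnal minimum and ARV involves absolute successive differences; both
  are nonlinear in the noise, so the baseline surge amplitude, the surge
  shifts and the reading-noise factors are tuned by a seeded stochastic
  fixed-point iteration against the programmed targets
  (``calibrate_mc_scalars``).  The resulting five scalars are frozen in
  ``FROZEN_MC`` so that ``default_config()`` is instant and deterministic;
  re-running the calibration reproduces them to Monte-Carlo precision.

Reading-noise SDs come from the closed form E[ARV] = 2*sigma/sqrt(pi) for
iid noise around a locally flat profile, inverted at the study's baseline
daytime and night-time ARV levels.
"""

from __future__ import annotations

import math

import numpy as np

from .metrics import average_real_variability, morning_surge
from .model import segment_windows
from .simulate import (
    EffectShift,
    SamplingSchedule,
    SimConfig,
    SubjectParams,
    day_indicator,
    simulate_profile,
    surge_bump,
    trough_bump,
)

__all__ = [
    "STUDY_TARGETS",
    "NOISE_SD",
    "FROZEN_MC",
    "shape_means",
    "solve_levels",
    "solve_shifts",
    "calibrate_mc_scalars",
    "build_default_config",
]

#: Reference group-level conditions the default cohort is calibrated to:
#: baseline window means and morning surge per group, and the training /
#: detraining group-mean changes in the training arm (mmHg; ARV changes in
#: mmHg of 24-h SBP ARV).  Changes are relative to baseline.
STUDY_TARGETS: dict = {
    "levels": {
        "TG-DT": {
            "day_sbp": 125.0, "night_sbp": 110.0, "mbps": 22.0,
            "day_dbp": 67.0, "night_dbp": 55.0,
        },
        "CON": {
            "day_sbp": 126.0, "night_sbp": 107.0, "mbps": 20.0,
            "day_dbp": 68.0, "night_dbp": 57.0,
        },
    },
    "changes": {
        ("TG-DT", "mid"): {
            "d24_sbp": -8.0, "dnight_sbp": -1.0, "dmbps": -6.0,
            "darv24_sbp": -2.16, "d24_dbp": -1.0, "dnight_dbp": 0.0,
        },
        ("TG-DT", "end"): {
            "d24_sbp": -6.0, "dnight_sbp": -1.0, "dmbps": -6.0,
            "darv24_sbp": -1.88, "d24_dbp": 1.0, "dnight_dbp": 0.0,
        },
    },
}

#: Reading-noise SDs (mmHg) from the ARV closed form sigma = ARV*sqrt(pi)/2
#: at the baseline daytime / night-time ARV of each channel.
NOISE_SD = {
    "day_sbp": 10.84 * math.sqrt(math.pi) / 2.0,   # ~9.61
    "night_sbp": 7.92 * math.sqrt(math.pi) / 2.0,  # ~7.02
    "day_dbp": 8.19 * math.sqrt(math.pi) / 2.0,    # ~7.26
    "night_dbp": 8.03 * math.sqrt(math.pi) / 2.0,  # ~7.12
}

TROUGH_DEPTH = 8.0       # structural nocturnal dip below night level (mmHg)
DBP_TROUGH_DEPTH = 4.0
HR_MEAN = 68.0

#: Monte-Carlo-calibrated scalars (see calibrate_mc_scalars): baseline surge
#: amplitude per group, and surge shift / noise factor per effect timepoint.
#: Values produced by ``calibrate_mc_scalars(n_subjects=6000, seed=20220909)``.
FROZEN_MC: dict = {
    "surge_amp": {"TG-DT": 0.3574, "CON": -9.2044},
    "surge_shift": {("TG-DT", "mid"): 5.6596, ("TG-DT", "end"): 1.5683},
    "noise_factor": {("TG-DT", "mid"): 0.7860, ("TG-DT", "end"): 0.8142},
}


def shape_means(schedule: SamplingSchedule | None = None) -> dict[str, float]:
    """Schedule averages of the shape functions over each window."""
    schedule = schedule or SamplingSchedule()
    u = schedule.offsets_hours()
    day = schedule.day_mask()
    s = day_indicator(u, schedule.day_length_h)
    t = trough_bump(u, schedule.trough_offset_h())
    m = surge_bump(u)
    morning = day & (u < 2.0)
    out: dict[str, float] = {}
    for name, mask in (("day", day), ("night", ~day), ("all", slice(None)),
                       ("morning", morning)):
        out[f"s_{name}"] = float(s[mask].mean())
        out[f"t_{name}"] = float(t[mask].mean())
        out[f"m_{name}"] = float(m[mask].mean())
    return out


def solve_levels(
    day_mean: float,
    night_mean: float,
    trough_depth: float,
    surge_amp: float,
    shapes: dict[str, float],
) -> tuple[float, float]:
    """Day/night structural levels whose expected window means hit the targets."""
    a = np.array(
        [[shapes["s_day"], 1.0 - shapes["s_day"]],
         [shapes["s_night"], 1.0 - shapes["s_night"]]]
    )
    b = np.array(
        [day_mean + trough_depth * shapes["t_day"] - surge_amp * shapes["m_day"],
         night_mean + trough_depth * shapes["t_night"] - surge_amp * shapes["m_night"]]
    )
    level_day, level_night = np.linalg.solve(a, b)
    return float(level_day), float(level_night)


def solve_shifts(
    d24: float, dnight: float, surge_shift: float, shapes: dict[str, float]
) -> tuple[float, float]:
    """Day/night level shifts realising programmed 24-h and night-mean changes."""
    a = np.array(
        [[shapes["s_all"], 1.0 - shapes["s_all"]],
         [shapes["s_night"], 1.0 - shapes["s_night"]]]
    )
    b = np.array(
        [d24 - surge_shift * shapes["m_all"],
         dnight - surge_shift * shapes["m_night"]]
    )
    day_shift, night_shift = np.linalg.solve(a, b)
    return float(day_shift), float(night_shift)


def _baseline_params(group: str, surge_amp: float, shapes, targets) -> SubjectParams:
    lv = targets["levels"][group]
    day_sbp, night_sbp = solve_levels(
        lv["day_sbp"], lv["night_sbp"], TROUGH_DEPTH, surge_amp, shapes
    )
    day_dbp, night_dbp = solve_levels(
        lv["day_dbp"], lv["night_dbp"], DBP_TROUGH_DEPTH, 0.0, shapes
    )
    return SubjectParams(
        day_sbp=day_sbp, night_sbp=night_sbp,
        trough_depth=TROUGH_DEPTH, surge_amp=surge_amp,
        day_dbp=day_dbp, night_dbp=night_dbp,
        dbp_trough_depth=DBP_TROUGH_DEPTH, dbp_surge_amp=0.0,
        sd_day_sbp=NOISE_SD["day_sbp"], sd_night_sbp=NOISE_SD["night_sbp"],
        sd_day_dbp=NOISE_SD["day_dbp"], sd_night_dbp=NOISE_SD["night_dbp"],
        hr_mean=HR_MEAN,
    )


def _effect_shift(key, surge_shift, noise_factor, shapes, targets) -> EffectShift:
    tg = targets["changes"][key]
    day_shift, night_shift = solve_shifts(
        tg["d24_sbp"], tg["dnight_sbp"], surge_shift, shapes
    )
    dbp_day, dbp_night = solve_shifts(tg["d24_dbp"], tg["dnight_dbp"], 0.0, shapes)
    return EffectShift(
        day_shift=day_shift, night_shift=night_shift, surge_shift=surge_shift,
        noise_factor=noise_factor, dbp_day_shift=dbp_day, dbp_night_shift=dbp_night,
    )


def _rec_stats(rec) -> tuple[float, float]:
    w = segment_windows(rec)
    return (
        morning_surge(w).surge,
        average_real_variability(w, "24h", "sbp", weighted=True),
    )


def calibrate_mc_scalars(
    n_subjects: int = 6000,
    seed: int = 20220909,
    n_iter: int = 4,
    schedule: SamplingSchedule | None = None,
    targets: dict | None = None,
    verbose: bool = False,
) -> dict:
    """Stochastic fixed-point calibration of the nonlinear scalars.

    Uses common random numbers: each pseudo-subject's reading-noise draws are
    reused across the baseline and shifted visits, so the paired-change
    estimates that drive the updates have very small Monte-Carlo error.
    Newton steps use the analytic sensitivities — the morning-window average
    of the surge bump for the surge scalars, and the current baseline ARV for
    the noise factors.
    """
    import warnings

    schedule = schedule or SamplingSchedule()
    targets = targets or STUDY_TARGETS
    shapes = shape_means(schedule)
    c_surge = shapes["m_morning"] - shapes["m_night"]
    diary = schedule.diary()

    surge_amp = {g: 0.0 for g in targets["levels"]}
    effect_keys = list(targets["changes"])
    surge_shift = {k: 0.0 for k in effect_keys}
    noise_factor = {
        k: 1.0 + targets["changes"][k]["darv24_sbp"] / 10.0 for k in effect_keys
    }

    def simulate_stats(params, scale_seed_offset):
        mbps = np.empty(n_subjects)
        arv = np.empty(n_subjects)
        for i in range(n_subjects):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, scale_seed_offset, i])
            )
            rec = simulate_profile(params, schedule, diary, rng)
            mbps[i], arv[i] = _rec_stats(rec)
        return mbps, arv

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for it in range(n_iter):
            base_stats = {}
            for g_idx, g in enumerate(targets["levels"]):
                base = _baseline_params(g, surge_amp[g], shapes, targets)
                mbps_b, arv_b = simulate_stats(base, g_idx)
                base_stats[g] = (mbps_b, arv_b)
                resid = targets["levels"][g]["mbps"] - mbps_b.mean()
                surge_amp[g] += resid / c_surge
                if verbose:
                    print(f"iter {it} {g}: E[MBPS]={mbps_b.mean():.3f} "
                          f"-> surge_amp={surge_amp[g]:.4f}")
            for key in effect_keys:
                g = key[0]
                g_idx = list(targets["levels"]).index(g)
                base = _baseline_params(g, surge_amp[g], shapes, targets)
                eff = _effect_shift(
                    key, surge_shift[key], noise_factor[key], shapes, targets
                )
                mbps_b, arv_b = base_stats[g]
                mbps_s, arv_s = simulate_stats(eff.apply(base), g_idx)
                dmbps = (mbps_s - mbps_b).mean()
                darv = (arv_s - arv_b).mean()
                tg = targets["changes"][key]
                surge_shift[key] += (tg["dmbps"] - dmbps) / c_surge
                noise_factor[key] += (tg["darv24_sbp"] - darv) / arv_b.mean()
                if verbose:
                    print(f"iter {it} {key}: dMBPS={dmbps:.3f} dARV={darv:.3f} "
                          f"-> surge_shift={surge_shift[key]:.4f} "
                          f"noise_factor={noise_factor[key]:.4f}")
    return {
        "surge_amp": surge_amp,
        "surge_shift": surge_shift,
        "noise_factor": noise_factor,
    }


def build_default_config(seed: int = 0, mc: dict | None = None, **overrides) -> SimConfig:
    """Assemble the calibrated study-default :class:`SimConfig`.

    ``overrides`` replace SimConfig fields (e.g. ``n_per_group``,
    ``missingness``) after calibration; pass ``mc`` to use freshly calibrated
    scalars instead of the frozen ones.
    """
    schedule = overrides.pop("schedule", SamplingSchedule())
    shapes = shape_means(schedule)
    mc = mc or FROZEN_MC
    levels = {
        g: _baseline_params(g, mc["surge_amp"][g], shapes, STUDY_TARGETS)
        for g in STUDY_TARGETS["levels"]
    }
    effects = {(g, "baseline"): EffectShift() for g in STUDY_TARGETS["levels"]}
    for key in STUDY_TARGETS["changes"]:
        effects[key] = _effect_shift(
            key, mc["surge_shift"][key], mc["noise_factor"][key], shapes,
            STUDY_TARGETS,
        )
    cfg = SimConfig(
        n_per_group={"TG-DT": 13, "CON": 12},
        levels=levels,
        effects=effects,
        schedule=schedule,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.__post_init__()
    return cfg
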