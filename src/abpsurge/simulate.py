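"""Synthetic ABPM cohort generator.

Emulates a 2-group (training-detraining vs control) x 3-timepoint
(baseline / post-training / post-detraining) trial in young normotensives:
each subject-visit is a 24-h recording sampled every 30 min while awake and
hourly during sleep, drawn from a smooth parametric circadian profile

    SBP(u) = L_night + (L_day - L_night) * S(u) - D * T(u) + A * M(u) + eps

with ``u`` hours since waking, ``S`` a logistic day indicator switching at
the wake and bed times, ``T`` a Gaussian nocturnal-trough bump centred at
03:30, ``M`` a Gaussian post-wake morning bump, and iid reading noise whose
standard deviation differs between day and night (reading-to-reading
variability is larger while awake).  DBP follows the same shape with its own
levels.  The profile is deliberately not a cosinor: day level, trough and
surge are separately controllable, so the generator can write an exact
ground-truth table for recovery testing.

Subject heterogeneity enters as a per-subject level intercept (shared by all
visits) plus a per-visit day-to-day level shift; group x timepoint training
effects are additive shifts on the day level, night level and surge
amplitude, plus a multiplicative factor on the reading-noise SD.  All
randomness flows from a single seed through per-subject substreams, so
growing the cohort does not reshuffle existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Mapping

import numpy as np
from scipy.special import expit

from .model import ABPMRecording, BPReading, SleepDiary, TIMEPOINTS

__all__ = [
    "SamplingSchedule",
    "SubjectParams",
    "EffectShift",
    "SimConfig",
    "day_indicator",
    "trough_bump",
    "surge_bump",
    "profile_values",
    "expected_window_means",
    "simulate_profile",
    "simulate_cohort",
    "default_config",
]

GROUPS = ("TG-DT", "CON")

# Shape constants (hours).  The wake/bed transitions are logistic with scale
# 0.1 h (10-90% width ~26 min) centred 15 min before the diary time, so the
# readings taken exactly at wake and bed sit almost entirely on their own
# side of the boundary.  The nocturnal trough is centred at 03:30 with SD
# 1 h; the morning bump peaks 45 min after waking with SD 40 min.
TRANSITION_SCALE_H = 0.1
TRANSITION_LEAD_H = 0.25
TROUGH_CLOCK_H = 3.5
TROUGH_SD_H = 1.0
SURGE_PEAK_H = 0.75
SURGE_SD_H = 2.0 / 3.0


@dataclass(frozen=True)
class SamplingSchedule:
    """Reading times of the simulated monitor, anchored to the diary."""

    wake: time = time(7, 0)
    bed: time = time(23, 0)
    day_step_min: int = 30
    night_step_min: int = 60
    start_date: date = date(2022, 1, 10)

    @property
    def day_length_h(self) -> float:
        delta = (
            datetime.combine(self.start_date, self.bed)
            - datetime.combine(self.start_date, self.wake)
        )
        return delta.total_seconds() / 3600.0

    def offsets_hours(self) -> np.ndarray:
        """Reading offsets (h since wake) over the nominal 24-h day."""
        day = np.arange(0.0, self.day_length_h, self.day_step_min / 60.0)
        night = np.arange(self.day_length_h, 24.0, self.night_step_min / 60.0)
        return np.concatenate([day, night])

    def day_mask(self) -> np.ndarray:
        off = self.offsets_hours()
        return off < self.day_length_h

    def diary(self, day_offset: int = 0) -> SleepDiary:
        wake_dt = datetime.combine(
            self.start_date + timedelta(days=day_offset), self.wake
        )
        return SleepDiary(wake_time=wake_dt, bed_time=wake_dt + timedelta(hours=self.day_length_h))

    def trough_offset_h(self) -> float:
        return (TROUGH_CLOCK_H - (self.wake.hour + self.wake.minute / 60.0)) % 24.0


def day_indicator(u: np.ndarray, day_length_h: float) -> np.ndarray:
    """Smooth 0/1 indicator of the awake period, in hours since wake."""
    u = np.asarray(u, dtype=float)
    rise = expit((u + TRANSITION_LEAD_H) / TRANSITION_SCALE_H)
    fall = expit((day_length_h - TRANSITION_LEAD_H - u) / TRANSITION_SCALE_H)
    return rise * fall


def trough_bump(u: np.ndarray, trough_offset_h: float) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.exp(-0.5 * ((u - trough_offset_h) / TROUGH_SD_H) ** 2)


def surge_bump(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.exp(-0.5 * ((u - SURGE_PEAK_H) / SURGE_SD_H) ** 2)


@dataclass(frozen=True)
class SubjectParams:
    """Structural profile parameters for one recording (pre-noise truth)."""

    day_sbp: float
    night_sbp: float
    trough_depth: float
    surge_amp: float
    day_dbp: float
    night_dbp: float
    dbp_trough_depth: float
    dbp_surge_amp: float
    sd_day_sbp: float
    sd_night_sbp: float
    sd_day_dbp: float
    sd_night_dbp: float
    hr_mean: float
    hr_night_drop: float = 8.0
    sd_hr: float = 7.0


@dataclass(frozen=True)
class EffectShift:
    """Additive group x timepoint training effect on the SBP/DBP profile."""

    day_shift: float = 0.0
    night_shift: float = 0.0
    surge_shift: float = 0.0
    noise_factor: float = 1.0
    dbp_day_shift: float = 0.0
    dbp_night_shift: float = 0.0

    def apply(self, p: SubjectParams) -> SubjectParams:
        return replace(
            p,
            day_sbp=p.day_sbp + self.day_shift,
            night_sbp=p.night_sbp + self.night_shift,
            surge_amp=p.surge_amp + self.surge_shift,
            day_dbp=p.day_dbp + self.dbp_day_shift,
            night_dbp=p.night_dbp + self.dbp_night_shift,
            sd_day_sbp=p.sd_day_sbp * self.noise_factor,
            sd_night_sbp=p.sd_night_sbp * self.noise_factor,
        )


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic cohort."""

    n_per_group: Mapping[str, int]
    levels: Mapping[str, SubjectParams]          # group -> baseline profile
    effects: Mapping[tuple[str, str], EffectShift]  # (group, timepoint) ->
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)
    timepoints: tuple[str, ...] = TIMEPOINTS
    between_subject_sd: float = 6.8      # SBP level intercept across subjects
    dbp_between_sd: float = 6.0
    visit_sd: float = 2.4                # day-to-day SBP level shift per visit
    dbp_visit_sd: float = 2.0
    hr_between_sd: float = 10.0
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.n_per_group:
            if g not in self.levels:
                raise ValueError(f"no baseline levels for group {g!r}")
        for (g, tp), eff in self.effects.items():
            if tp == self.timepoints[0] and eff != EffectShift():
                raise ValueError("effects at baseline must be zero")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")


def profile_values(
    params: SubjectParams, schedule: SamplingSchedule
) -> dict[str, np.ndarray]:
    """Noise-free SBP/DBP/HR profile evaluated at the scheduled offsets."""
    u = schedule.offsets_hours()
    s = day_indicator(u, schedule.day_length_h)
    t = trough_bump(u, schedule.trough_offset_h())
    m = surge_bump(u)
    sbp = params.night_sbp + (params.day_sbp - params.night_sbp) * s
    sbp = sbp - params.trough_depth * t + params.surge_amp * m
    dbp = params.night_dbp + (params.day_dbp - params.night_dbp) * s
    dbp = dbp - params.dbp_trough_depth * t + params.dbp_surge_amp * m
    hr = params.hr_mean - params.hr_night_drop * (1.0 - s)
    return {"u": u, "sbp": sbp, "dbp": dbp, "hr": hr}


def expected_window_means(
    params: SubjectParams, schedule: SamplingSchedule
) -> dict[str, float]:
    """Exact pre-noise window means implied by the profile and schedule."""
    prof = profile_values(params, schedule)
    day = schedule.day_mask()
    out = {}
    for ch in ("sbp", "dbp"):
        vals = prof[ch]
        out[f"day_{ch}"] = float(vals[day].mean())
        out[f"night_{ch}"] = float(vals[~day].mean())
        out[f"mean24_{ch}"] = float(vals.mean())
    return out


def simulate_profile(
    params: SubjectParams,
    schedule: SamplingSchedule,
    diary: SleepDiary,
    rng: np.random.Generator,
    subject_id: str = "S01",
    timepoint: str = "baseline",
    missingness: float = 0.0,
) -> ABPMRecording:
    """Draw one noisy recording from the profile on the sampling schedule.

    Noise draws are taken in a fixed order (SBP, DBP, HR, then missingness),
    so two calls with generators in the same state produce bit-identical
    recordings.
    """
    prof = profile_values(params, schedule)
    u = prof["u"]
    day = schedule.day_mask()
    sd_sbp = np.where(day, params.sd_day_sbp, params.sd_night_sbp)
    sd_dbp = np.where(day, params.sd_day_dbp, params.sd_night_dbp)
    n = u.size
    sbp = prof["sbp"] + sd_sbp * rng.standard_normal(n)
    dbp = prof["dbp"] + sd_dbp * rng.standard_normal(n)
    hr = prof["hr"] + params.sd_hr * rng.standard_normal(n)
    # keep pressures physiological: widen any crossed pair symmetrically
    crossed = sbp <= dbp
    if crossed.any():
        mid = (sbp + dbp) / 2.0
        sbp = np.where(crossed, mid + 5.0, sbp)
        dbp = np.where(crossed, mid - 5.0, dbp)
    keep = np.ones(n, dtype=bool)
    if missingness > 0.0:
        keep = rng.random(n) >= missingness
        if keep.sum() < 2:
            keep[:2] = True
    readings = [
        BPReading(
            timestamp=diary.wake_time + timedelta(hours=float(u[k])),
            sbp=float(np.round(sbp[k], 6)),
            dbp=float(np.round(dbp[k], 6)),
            hr=float(np.round(max(hr[k], 30.0), 6)),
            valid=True,
        )
        for k in range(n)
        if keep[k]
    ]
    return ABPMRecording(
        subject_id=subject_id, timepoint=timepoint, readings=readings, diary=diary
    )


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def simulate_cohort(cfg: SimConfig):
    """Simulate the full cohort.

    Returns ``(recordings, design, truth)`` where ``design`` is a DataFrame
    mapping subject to group and ``truth`` holds, per subject-visit, the
    structural profile parameters and the exact pre-noise window means.
    """
    import pandas as pd

    recordings: list[ABPMRecording] = []
    design_rows = []
    truth_rows = []
    for g_idx, group in enumerate(cfg.n_per_group):
        base = cfg.levels[group]
        for s_idx in range(int(cfg.n_per_group[group])):
            sid = f"{group}-{s_idx + 1:02d}"
            srng = _substream(cfg.seed, g_idx, s_idx, 0)
            icpt_sbp = cfg.between_subject_sd * srng.standard_normal()
            icpt_dbp = cfg.dbp_between_sd * srng.standard_normal()
            hr_i = base.hr_mean + cfg.hr_between_sd * srng.standard_normal()
            design_rows.append({"subject_id": sid, "group": group})
            for v_idx, tp in enumerate(cfg.timepoints):
                vrng = _substream(cfg.seed, g_idx, s_idx, 1 + v_idx)
                visit_sbp = cfg.visit_sd * vrng.standard_normal()
                visit_dbp = cfg.dbp_visit_sd * vrng.standard_normal()
                eff = cfg.effects.get((group, tp), EffectShift())
                p = eff.apply(
                    replace(
                        base,
                        day_sbp=base.day_sbp + icpt_sbp + visit_sbp,
                        night_sbp=base.night_sbp + icpt_sbp + visit_sbp,
                        day_dbp=base.day_dbp + icpt_dbp + visit_dbp,
                        night_dbp=base.night_dbp + icpt_dbp + visit_dbp,
                        hr_mean=hr_i,
                    )
                )
                diary = cfg.schedule.diary(day_offset=56 * v_idx)
                rec = simulate_profile(
                    p, cfg.schedule, diary, vrng,
                    subject_id=sid, timepoint=tp, missingness=cfg.missingness,
                )
                recordings.append(rec)
                exp = expected_window_means(p, cfg.schedule)
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "timepoint": tp,
                        "true_day_sbp": p.day_sbp,
                        "true_night_sbp": p.night_sbp,
                        "true_surge_amp": p.surge_amp,
                        "true_sd_day_sbp": p.sd_day_sbp,
                        "true_sd_night_sbp": p.sd_night_sbp,
                        **{f"expected_{k}": v for k, v in exp.items()},
                    }
                )
    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame(truth_rows)
    return recordings, design, truth


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The calibrated study-default configuration (see ``calibrate``)."""
    from .calibrate import build_default_config

    return build_default_config(seed=seed, **overrides)
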