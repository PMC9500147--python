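"""Per-recording statistics: resting selection, window means, MBPS, ARV, dip."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abpsurge.metrics import (
    average_real_variability,
    compute_metrics,
    morning_surge,
    nocturnal_dip,
    resting_bp,
    window_mean,
)
from abpsurge.model import BPReading, segment_windows

from conftest import make_recording, reading


def triplet(*pairs):
    return [reading(i, s, d) for i, (s, d) in enumerate(pairs)]


class TestRestingBP:
    @pytest.mark.parametrize(
        "pairs,exp_sbp,exp_dbp,exp_map",
        [
            # per-channel minima; MAP = dbp + (sbp - dbp)/3
            ([(120, 80), (118, 76), (122, 78)], 118, 76, 90.0),
            ([(123, 69)] * 3, 123, 69, 87.0),
            ([(130, 70), (124, 74), (126, 66)], 124, 66, 66 + 58 / 3),
        ],
    )
    def test_examples(self, pairs, exp_sbp, exp_dbp, exp_map):
        res = resting_bp(triplet(*pairs))
        assert res.sbp == exp_sbp
        assert res.dbp == exp_dbp
        assert res.map == pytest.approx(exp_map)

    def test_requires_three_readings(self):
        with pytest.raises(ValueError, match="exactly 3"):
            resting_bp(triplet((120, 80), (118, 76)))


def two_window_recording(day_vals, night_vals):
    rs = [reading(30 * k, v) for k, v in enumerate(day_vals)]
    rs += [reading(16 * 60 + 60 * k, v) for k, v in enumerate(night_vals)]
    return segment_windows(make_recording(rs))


class TestWindowMean:
    def test_constant_series(self):
        w = two_window_recording([120, 120], [120])
        for window in ("24h", "day", "night"):
            assert window_mean(w, window, "sbp") == 120

    def test_arithmetic(self):
        w = two_window_recording([120, 130], [100])
        assert window_mean(w, "day", "sbp") == 125
        assert window_mean(w, "24h", "sbp") == pytest.approx(350 / 3)

    def test_matches_bruteforce_on_simulated_recording(self):
        # oracle: independent summation over the indexed readings
        from abpsurge.calibrate import build_default_config
        from abpsurge.simulate import simulate_cohort

        cfg = build_default_config(seed=5, n_per_group={"TG-DT": 1})
        rec = simulate_cohort(cfg)[0][0]
        w = segment_windows(rec)
        sbp = rec.channel("sbp")
        assert window_mean(w, "day", "sbp") == pytest.approx(
            sbp[w.day_idx].mean(), abs=1e-12
        )
        assert window_mean(w, "night", "sbp") == pytest.approx(
            sbp[w.night_idx].mean(), abs=1e-12
        )

    def test_empty_window_errors(self):
        w = two_window_recording([120, 121], [100])
        w.recording.readings[-1] = BPReading(
            w.recording.readings[-1].timestamp, 100, 70, valid=False
        )
        with pytest.raises(ValueError, match="night"):
            window_mean(w, "night", "sbp")


def surge_recording(morning, nocturnal, trough_hours=None):
    """Morning SBP readings at 30-min cadence post-wake; nocturnal hourly."""
    rs = [reading(30 * k, v) for k, v in enumerate(morning)]
    hours = trough_hours or [16 + 2 * k for k in range(len(nocturnal))]
    rs += [reading(60 * h, v) for h, v in zip(hours, nocturnal)]
    return segment_windows(make_recording(rs))


class TestMorningSurge:
    def test_hand_enumerated_example(self):
        # wake 07:00; morning 120,124,126,130 -> 125; nocturnal 108,104,100,106:
        # lowest 100, smaller neighbour 104 -> trough (100+104)/2 = 102; surge 23
        w = surge_recording([120, 124, 126, 130], [108, 104, 100, 106])
        res = morning_surge(w)
        assert res.morning_mean == 125
        assert res.trough_mean == 102
        assert res.surge == 23
        assert res.n_morning == 4

    def test_flat_profile_zero_surge(self):
        w = surge_recording([110] * 4, [110] * 4)
        assert morning_surge(w).surge == 0

    def test_trough_rule_variants(self):
        w = surge_recording([120, 124, 126, 130], [108, 104, 100, 106])
        assert morning_surge(w, "kario3").trough_mean == pytest.approx(310 / 3)
        assert morning_surge(w, "lowest1").trough_mean == 100

    def test_neighbour_tie_prefers_earlier(self):
        w = surge_recording([120] * 4, [106, 100, 106, 108])
        res = morning_surge(w)
        assert res.trough_mean == 103
        # earlier neighbour (index 0) chosen on the value tie
        assert res.trough_timestamps[0] < res.trough_timestamps[1]

    def test_warns_when_morning_count_not_four(self):
        w = surge_recording([120, 124], [108, 104, 100])
        with pytest.warns(UserWarning, match="expected 4"):
            morning_surge(w)

    def test_no_nocturnal_readings_errors(self):
        rs = [reading(30 * k, 120) for k in range(4)]
        rs += [reading(16 * 60 + 60, 100, valid=False),
               reading(17 * 60 + 60, 100, valid=False)]
        w = segment_windows(make_recording(rs))
        with pytest.raises(ValueError, match="nocturnal"):
            morning_surge(w)

    def test_translation_invariance(self):
        w1 = surge_recording([120, 124, 126, 130], [108, 104, 100, 106])
        shifted = [
            BPReading(r.timestamp, r.sbp + 17.5, r.dbp, r.hr, r.valid)
            for r in w1.recording.readings
        ]
        w2 = segment_windows(make_recording(shifted))
        assert morning_surge(w2).surge == pytest.approx(morning_surge(w1).surge)


class TestARV:
    def test_constant_series_zero(self):
        w = two_window_recording([120] * 6, [120] * 3)
        assert average_real_variability(w, "24h", "sbp") == 0

    def test_unweighted_equal_spacing(self):
        rs = [reading(30 * k, v) for k, v in enumerate([120, 110, 130])]
        w = segment_windows(make_recording(rs))
        assert average_real_variability(w, "day", "sbp", weighted=False) == 15

    def test_weighted_unequal_gaps(self):
        # gaps 0.5 h then 1.0 h: (0.5*10 + 1.0*20) / 1.5
        rs = [reading(0, 120), reading(30, 110), reading(90, 130)]
        w = segment_windows(make_recording(rs))
        assert average_real_variability(w, "day", "sbp") == pytest.approx(50 / 3)

    def test_weighted_equals_unweighted_for_equal_gaps(self):
        rng = np.random.default_rng(2)
        vals = 120 + 8 * rng.standard_normal(12)
        rs = [reading(30 * k, v) for k, v in enumerate(vals)]
        w = segment_windows(make_recording(rs))
        assert average_real_variability(w, "day", "sbp", True) == pytest.approx(
            average_real_variability(w, "day", "sbp", False), abs=1e-12
        )

    def test_requires_two_readings(self):
        w = two_window_recording([120, 121], [100])
        with pytest.raises(ValueError, match="ARV"):
            average_real_variability(w, "night", "sbp")

    def test_no_pair_spans_day_night_boundary(self):
        # day 100, 140 and night 90, 90: night ARV must ignore the 140 -> 90
        # transition; 24-h ARV includes it
        w = two_window_recording([100, 140], [90, 90])
        assert average_real_variability(w, "night", "sbp", weighted=False) == 0
        assert average_real_variability(w, "day", "sbp", weighted=False) == 40
        assert average_real_variability(w, "24h", "sbp", weighted=False) == pytest.approx(
            (40 + 50 + 0) / 3
        )

    def test_prewake_night_readings_form_separate_run(self):
        # night readings before waking must not pair with post-bed readings
        rs = [reading(-60, 100), reading(0, 130), reading(30, 131),
              reading(16 * 60, 90), reading(17 * 60, 96)]
        w = segment_windows(make_recording(rs))
        # pairs: (90, 96) only in the post-bed run; prewake reading unpaired
        assert average_real_variability(w, "night", "sbp", weighted=False) == 6

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 5.0),
        vals=st.lists(st.floats(60, 200), min_size=3, max_size=12),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_translation_and_scale_equivariance(self, shift, scale, vals):
        def arv_of(values):
            rs = [reading(30 * k, v, 20.0) for k, v in enumerate(values)]
            w = segment_windows(make_recording(rs))
            return average_real_variability(w, "day", "sbp")

        base = arv_of(vals)
        assert base >= 0
        assert arv_of([v + shift for v in vals]) == pytest.approx(base, abs=1e-9)
        assert arv_of([v * scale for v in vals]) == pytest.approx(
            scale * base, rel=1e-9
        )

    def test_expected_arv_of_iid_noise_is_2_sigma_over_sqrt_pi(self):
        # Monte-Carlo check of E[ARV] -> 2*sigma/sqrt(pi) on a flat profile
        sigma = 9.6
        rng = np.random.default_rng(7)
        n_rec, n_read = 400, 49
        draws = 120 + sigma * rng.standard_normal((n_rec, n_read))
        arvs = np.abs(np.diff(draws, axis=1)).mean(axis=1)
        expected = 2 * sigma / np.sqrt(np.pi)
        se = arvs.std(ddof=1) / np.sqrt(n_rec)
        assert abs(arvs.mean() - expected) < 3 * se
        # and the package computes the same statistic on one recording
        rs = [reading(30 * k, v) for k, v in enumerate(draws[0, :32])]
        w = segment_windows(make_recording(rs))
        assert average_real_variability(w, "day", "sbp", weighted=False) == (
            pytest.approx(np.abs(np.diff(draws[0, :32])).mean())
        )


class TestNocturnalDip:
    @pytest.mark.parametrize(
        "day,night,expected",
        [([125] * 2, [110], 12.0), ([120] * 2, [120], 0.0), ([100] * 2, [80], 20.0)],
    )
    def test_examples(self, day, night, expected):
        w = two_window_recording(day, night)
        assert nocturnal_dip(w) == pytest.approx(expected)


class TestComputeMetrics:
    def test_matches_scripted_recomputation(self):
        from abpsurge.calibrate import build_default_config
        from abpsurge.simulate import simulate_cohort

        cfg = build_default_config(seed=9, n_per_group={"TG-DT": 1})
        rec = simulate_cohort(cfg)[0][0]
        row = compute_metrics(rec)
        w = segment_windows(rec)
        sbp, dbp = rec.channel("sbp"), rec.channel("dbp")
        assert row.mean_day_sbp == pytest.approx(sbp[w.day_idx].mean())
        assert row.mean_night_dbp == pytest.approx(dbp[w.night_idx].mean())
        assert row.mean_24h_sbp == pytest.approx(sbp.mean())
        assert row.lowest_night_sbp == pytest.approx(sbp[w.night_idx].min())
        assert row.dip_pct == pytest.approx(
            100 * (row.mean_day_sbp - row.mean_night_sbp) / row.mean_day_sbp
        )
        assert row.mbps == pytest.approx(morning_surge(w).surge)
        # independent weighted-ARV oracle over the full reading sequence
        gaps = np.diff(rec.timestamps().astype(float)) / 3600.0
        diffs = np.abs(np.diff(sbp))
        assert row.arv_24h_sbp == pytest.approx((gaps * diffs).sum() / gaps.sum())
        assert row.qc_passed

    def test_qc_failed_recording_still_yields_metrics(self, nominal_recording):
        rec = nominal_recording
        rec.readings = [
            BPReading(r.timestamp, r.sbp + k % 3, r.dbp, r.hr,
                      valid=not (8 <= k <= 20))
            for k, r in enumerate(rec.readings)
        ]
        row = compute_metrics(rec)
        assert row.qc_passed is False
        assert np.isfinite(row.mean_24h_sbp)

    def test_empty_night_window_errors(self):
        rs = [reading(30 * k, 120 + k) for k in range(10)]
        with pytest.raises(ValueError):
            compute_metrics(make_recording(rs))
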