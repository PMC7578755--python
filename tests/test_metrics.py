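import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gesturelat.metrics import (
    InsufficientDataError,
    MetricConfig,
    alternative_laterality,
    compute_gesture_metrics,
    detect_movements,
    magnitude_ratio_series,
    median_magnitude_ratio,
    movements_per_minute,
)
from gesturelat.simulate import SignalSimParams, simulate_session

from conftest import constant_recording, make_epochs, make_session, make_signal


def _bursty(fs=50.0, bursts=((2, 3),), level=0.5, total=20.0):
    mag = np.zeros(int(total * fs))
    for s, e in bursts:
        mag[int(s * fs):int(e * fs)] = level
    return make_signal(mag, fs=fs)


class TestDetectMovements:
    def test_silent_signal_no_events(self):
        assert detect_movements(make_signal(np.zeros(1000))) == []

    def test_three_separated_bursts(self):
        sig = _bursty(bursts=((1, 2), (7, 8), (13, 14)))
        ev = detect_movements(sig, 0.05, 0.25, 0.25)
        assert len(ev) == 3
        assert all(e.peak_mag_g == pytest.approx(0.5) for e in ev)

    def test_brief_dip_merged(self):
        sig = _bursty(bursts=((1.0, 2.0), (2.1, 3.0)))
        ev = detect_movements(sig, 0.05, 0.25, 0.25)
        assert len(ev) == 1
        assert ev[0].end_s - ev[0].start_s == pytest.approx(2.0, abs=0.1)

    def test_long_gap_not_merged(self):
        sig = _bursty(bursts=((1.0, 2.0), (2.5, 3.5)))
        ev = detect_movements(sig, 0.05, 0.25, 0.25)
        assert len(ev) == 2

    def test_short_blip_dropped(self):
        sig = _bursty(bursts=((1.0, 1.1),))
        assert detect_movements(sig, 0.05, 0.25, 0.25) == []

    def test_events_ordered_nonoverlapping(self, rng):
        mag = (rng.uniform(size=3000) > 0.7) * rng.uniform(0.1, 1.0, 3000)
        ev = detect_movements(make_signal(mag), 0.05, 0.1, 0.1)
        starts = [e.start_s for e in ev]
        assert starts == sorted(starts)
        assert all(a.end_s <= b.start_s for a, b in zip(ev, ev[1:]))

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_movements(make_signal(np.zeros(10)), 0.0)


class TestMovementsPerMinute:
    def test_rate(self):
        assert movements_per_minute(list(range(12)), 240.0) == pytest.approx(3.0)

    def test_no_events(self):
        assert movements_per_minute([], 120.0) == 0.0

    def test_zero_task_time_rejected(self):
        with pytest.raises(ValueError):
            movements_per_minute([], 0.0)

    def test_matches_recount(self, rng):
        for _ in range(10):
            n = int(rng.integers(0, 40))
            dur = float(rng.uniform(30, 600))
            assert movements_per_minute([object()] * n, dur) == pytest.approx(60.0 * n / dur)


class TestMagnitudeRatioSeries:
    def test_symmetric_epochs_zero(self):
        e = make_epochs([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert np.allclose(magnitude_ratio_series(e), 0.0)

    def test_doubled_nonpreferred_ln2(self):
        e = make_epochs([0.1, 0.2], [0.2, 0.4])
        assert np.allclose(magnitude_ratio_series(e), np.log(2))

    def test_unilateral_preferred_gets_minus_cap(self):
        e = make_epochs([0.2], [0.0])
        assert magnitude_ratio_series(e, cap=7.0).tolist() == [-7.0]

    def test_unilateral_nonpreferred_gets_plus_cap(self):
        e = make_epochs([0.0], [0.2])
        assert magnitude_ratio_series(e, cap=7.0).tolist() == [7.0]

    def test_both_inactive_excluded(self):
        e = make_epochs([0.0, 0.2], [0.0, 0.2])
        assert len(magnitude_ratio_series(e)) == 1

    def test_bilateral_ratio_clipped_to_cap(self):
        e = make_epochs([1e-6, 0.1], [1.0, 0.1], threshold=1e-7)
        r = magnitude_ratio_series(e, cap=7.0)
        assert r[0] == 7.0


class TestMedianMagnitudeRatio:
    def test_zeros(self):
        assert median_magnitude_ratio(np.zeros(12)) == 0.0

    def test_odd_length_median(self):
        assert median_magnitude_ratio([-1, -0.5, 0.2], min_count=1) == -0.5

    def test_too_few_epochs_flagged(self):
        with pytest.raises(InsufficientDataError):
            median_magnitude_ratio([0.1] * 9, min_count=10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-7, 7), min_size=1, max_size=30), st.just(None))
    def test_matches_sorting_oracle(self, vals, _):
        s = sorted(vals)
        n = len(s)
        expected = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
        assert median_magnitude_ratio(vals, min_count=1) == pytest.approx(expected)


class TestAlternativeLaterality:
    def test_symmetric(self):
        e = make_epochs([0.2, 0.3], [0.2, 0.3])
        assert alternative_laterality(e, "use_ratio") == 1.0
        assert alternative_laterality(e, "laterality_index") == 0.0

    def test_nonpreferred_silent(self):
        e = make_epochs([0.2, 0.3], [0.0, 0.0])
        assert alternative_laterality(e, "use_ratio") == 0.0
        assert alternative_laterality(e, "laterality_index") == -1.0

    def test_laterality_index_bounded(self, rng):
        for _ in range(20):
            e = make_epochs(rng.uniform(0, 0.5, 30), rng.uniform(0, 0.5, 30))
            assert -1.0 <= alternative_laterality(e, "laterality_index") <= 1.0

    def test_zero_denominator_flagged(self):
        e = make_epochs([0.0], [0.2])
        with pytest.raises(InsufficientDataError):
            alternative_laterality(e, "use_ratio")


class TestArmSwapAntisymmetry:
    def test_swap_negates_ratio_statistics(self, rng):
        e = make_epochs(rng.uniform(0, 0.5, 50), rng.uniform(0, 0.5, 50))
        sw = e.swapped()
        r, r_sw = magnitude_ratio_series(e), magnitude_ratio_series(sw)
        assert np.allclose(r_sw, -r)
        assert median_magnitude_ratio(r_sw) == -median_magnitude_ratio(r)
        assert alternative_laterality(sw, "laterality_index") == pytest.approx(
            -alternative_laterality(e, "laterality_index")
        )
        u, u_sw = (alternative_laterality(x, "use_ratio") for x in (e, sw))
        assert u_sw == pytest.approx(1.0 / u)

    def test_mmr_monotone_in_nonpreferred_magnitude(self, rng):
        mag1 = rng.uniform(0.05, 0.5, 40)
        mag2 = rng.uniform(0.05, 0.5, 40)
        base = median_magnitude_ratio(magnitude_ratio_series(make_epochs(mag1, mag2)))
        boosted = median_magnitude_ratio(magnitude_ratio_series(make_epochs(mag1, mag2 * 1.5)))
        assert boosted >= base


class TestComputeGestureMetrics:
    def test_recovers_injected_laterality(self):
        session, _ = simulate_session(SignalSimParams(seed=5, laterality_k=0.5))
        gm = compute_gesture_metrics(session)
        assert gm.mmr == pytest.approx(np.log(0.5), abs=0.08)
        assert gm.n_active_epochs >= gm.n_unilateral_epochs
        assert gm.moves_per_min_preferred > 0

    def test_symmetric_session_near_zero(self):
        session, _ = simulate_session(SignalSimParams(seed=6, laterality_k=1.0))
        gm = compute_gesture_metrics(session)
        assert abs(gm.mmr) < 0.05

    def test_quiet_session_yields_flagged_missing(self):
        a = constant_recording(10, arm_side="right", arm_role="intact")
        b = constant_recording(10, arm_side="left", arm_role="prosthesis")
        gm = compute_gesture_metrics(make_session(a, b))
        assert np.isnan(gm.mmr)
        assert "mmr" in gm.missing
        assert gm.moves_per_min_preferred == 0.0

    def test_config_fingerprint_tracks_thresholds(self):
        assert MetricConfig().fingerprint() != MetricConfig(move_threshold_g=0.1).fingerprint()

    def test_parameter_recovery_across_seeds(self):
        """Median recovered MMR across seeds within +-0.05 of ln k (>=100 active epochs)."""
        for k in (0.5, 2.0):
            mmrs = [
                compute_gesture_metrics(
                    simulate_session(SignalSimParams(seed=s, laterality_k=k))[0]
                ).mmr
                for s in range(50)
            ]
            assert np.median(mmrs) == pytest.approx(np.log(k), abs=0.05)
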