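"""Feature extractors against closed-form synthetic waveforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myoburst.features import (
    ap_metrics,
    classify_ca_regime,
    classify_regime,
    cluster_1d,
    detect_spikes,
    extrema_branches,
    interspike_intervals,
)
from conftest import synthetic_square_train


def _regime_of(t, v, window=None):
    spikes = detect_spikes((t, v))
    if window is None:
        window = (t[0] / 1000.0, t[-1] / 1000.0)
    isis, _ = interspike_intervals(spikes, window)
    ap = ap_metrics((t, v), spikes, window)
    label, burst, diag = classify_regime(t, v, spikes, isis, ap["amplitude"])
    return label, burst, diag


class TestDetectSpikes:
    def test_subthreshold_trace_empty(self):
        t = np.arange(0, 1000.0, 0.05)
        v = -70.0 + 5.0 * np.sin(t / 50.0)
        assert len(detect_spikes((t, v))) == 0

    def test_square_train_crossings_at_period_multiples(self):
        """Closed form: upward crossings of -40 occur at t = k*100 (within one
        sample).  The train starts high, so t = 0 is not an upward crossing."""
        t, v = synthetic_square_train()
        spikes = detect_spikes((t, v))
        assert len(spikes) == 19
        expected = 100.0 * np.arange(1, 20)
        assert np.max(np.abs(spikes - expected)) < 0.05
        isis, mean = interspike_intervals(spikes, (0.0, 2.0))
        assert np.allclose(isis, 100.0, atol=0.05)
        assert mean == pytest.approx(100.0, abs=0.05)

    def test_hysteresis_counts_shoulder_once(self):
        """Re-crossing V_th without dipping below the reset level: one spike."""
        t = np.arange(0.0, 30.0, 0.05)
        v = np.full_like(t, -80.0)
        v[(t >= 5) & (t < 10)] = 0.0     # spike
        v[(t >= 10) & (t < 12)] = -45.0  # shoulder between reset and threshold
        v[(t >= 12) & (t < 14)] = -20.0  # re-crossing without re-arming
        spikes = detect_spikes((t, v))
        assert len(spikes) == 1

    def test_reset_above_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes((np.arange(3.0), np.zeros(3)), v_th=-40, reset_level=-30)


class TestISI:
    def test_single_spike_flagged_undefined(self):
        isis, mean = interspike_intervals(np.array([100.0]), (0.0, 1.0))
        assert len(isis) == 0 and np.isnan(mean)

    def test_bursting_train_isi_multiset(self):
        """4 spikes 20 ms apart then a 500 ms gap, repeated: ISIs {20,20,20,500,...}."""
        burst = np.array([0.0, 20.0, 40.0, 60.0])
        spikes = np.concatenate([burst + 560.0 * k for k in range(5)])
        isis, _ = interspike_intervals(spikes, (0.0, 3.0))
        assert sorted(set(np.round(isis, 6))) == [20.0, 500.0]
        assert np.sum(isis == 500.0) == 4


class TestAPMetrics:
    def test_triangle_ap_geometry(self):
        """Rise -80->+20 mV in 1 ms, fall to -80 in 9 ms: amplitude 100 mV,
        APD50 = 1 + 4.5 ms from the upstroke (piecewise-linear closed form)."""
        dt = 0.01
        t = np.arange(0.0, 60.0, dt)
        v = np.full_like(t, -80.0)
        rise = (t >= 20.0) & (t < 21.0)
        fall = (t >= 21.0) & (t < 30.0)
        v[rise] = -80.0 + 100.0 * (t[rise] - 20.0)
        v[fall] = 20.0 - 100.0 / 9.0 * (t[fall] - 21.0)
        spikes = detect_spikes((t, v))
        m = ap_metrics((t, v), spikes)
        assert len(m["amplitude"]) == 1
        assert m["amplitude"][0] == pytest.approx(100.0, abs=0.2)
        assert m["apd50"][0] == pytest.approx(5.5, abs=0.05)

    def test_truncated_ap_omitted(self):
        t = np.arange(0.0, 10.0, 0.01)
        v = np.where(t > 5.0, 0.0, -80.0)  # rises and never repolarizes
        spikes = detect_spikes((t, v))
        m = ap_metrics((t, v), spikes)
        assert len(spikes) == 1 and len(m["apd50"]) == 0

    def test_paced_run_apd50_in_physiological_band(self, wt_paced_2s):
        """WT pacing at BCL 100 ms: short murine AP, APD50 ~ 4.5 ms."""
        spikes = detect_spikes(wt_paced_2s)
        m = ap_metrics(wt_paced_2s, spikes, (0.5, 2.0))
        assert 3.5 <= np.mean(m["apd50"]) <= 5.5
        assert 100.0 <= np.mean(m["amplitude"]) <= 130.0


class TestBranches:
    def test_constant_series_single_branch(self):
        t = np.arange(0.0, 1000.0, 1.0)
        b = extrema_branches((t, np.full_like(t, -45.0)))
        assert len(b["max_branches"]) == 1 == len(b["min_branches"])
        assert b["max_branches"][0] == -45.0

    def test_alternating_peaks_two_branches(self):
        t = np.arange(0.0, 2000.0, 1.0)
        x = np.sin(2 * np.pi * t / 100.0) * np.where((t // 100) % 2 == 0, 10.0, 20.0)
        b = extrema_branches((t, x), cluster_tol=0.5)
        assert len(b["max_branches"]) == 2
        assert sorted(np.round(b["max_branches"])) == [10.0, 20.0]

    def test_sine_single_branch_each(self):
        t = np.arange(0.0, 5000.0, 0.5)
        x = np.sin(2 * np.pi * t / 250.0)
        b = extrema_branches((t, x), cluster_tol=0.01)
        assert len(b["max_branches"]) == 1 and len(b["min_branches"]) == 1

    def test_cluster_1d_gap_splitting(self):
        reps, assign = cluster_1d([1.0, 1.1, 5.0, 5.2, 1.05], tol=0.5)
        assert len(reps) == 2
        assert assign[0] == assign[1] == assign[4] != assign[2]


class TestClassifier:
    def test_flat_trace_quiescent(self):
        t = np.arange(0.0, 10000.0, 1.0)
        label, _, _ = _regime_of(t, np.full_like(t, -80.0))
        assert label == "quiescent"

    def test_settled_depolarized_trace_is_block(self):
        t = np.arange(0.0, 10000.0, 1.0)
        label, _, _ = _regime_of(t, np.full_like(t, -45.0))
        assert label == "depolarized-block"

    def test_periodic_train_spiking(self):
        t, v = synthetic_square_train(duration_ms=5000.0)
        label, _, _ = _regime_of(t, v)
        assert label == "spiking"

    def test_bursting_train_detected_with_descriptors(self):
        t = np.arange(0.0, 10000.0, 0.05)
        v = np.full_like(t, -75.0)
        for k in range(8):                       # 4-spike trains every 1.2 s
            for j in range(4):
                s = 1200.0 * k + 40.0 * j
                v[(t >= s) & (t < s + 2.0)] = 10.0
        label, burst, _ = _regime_of(t, v)
        assert label == "bursting"
        assert burst["spikes_per_burst"] == pytest.approx(4.0)
        assert burst["interburst_interval_ms"] == pytest.approx(1080.0, rel=0.01)

    def test_amplitude_alternans_detected(self):
        t = np.arange(0.0, 10000.0, 0.05)
        v = np.full_like(t, -80.0)
        for k in range(24):
            s = 400.0 * k
            height = 20.0 if k % 2 == 0 else -10.0   # alternating amplitude
            v[(t >= s) & (t < s + 2.0)] = height
        label, _, _ = _regime_of(t, v)
        assert label == "alternans"

    @given(shift=st.floats(0.0, 5000.0), factor=st.sampled_from([1, 2]))
    @settings(max_examples=10, deadline=None)
    def test_regime_invariant_to_shift_and_resampling(self, shift, factor):
        """Uniform time shift and 2x resampling do not change the label."""
        t, v = synthetic_square_train(duration_ms=5000.0, dt=0.1)
        base, _, _ = _regime_of(t, v)
        t2 = np.arange(0.0, 5000.0, 0.1 / factor)
        v2 = np.where(((t2) % 100.0) < 2.0, 20.0, -80.0).astype(float)
        lbl, _, _ = _regime_of(t2 + shift, v2)
        assert lbl == base == "spiking"


class TestCaClassifier:
    def test_constant_peaks_periodic(self):
        assert classify_ca_regime(np.full(20, 0.5))[0] == "periodic"

    def test_interleaved_two_level_peaks_alternans(self):
        peaks = np.tile([0.4, 0.6], 10)
        assert classify_ca_regime(peaks)[0] == "alternans"

    def test_large_spread_multibranch_bursting(self):
        peaks = np.concatenate([np.full(5, 1.0), np.full(5, 0.2),
                                np.full(5, 0.95), np.full(5, 0.25)])
        rng = np.random.default_rng(0)
        peaks = peaks + rng.normal(0, 0.01, peaks.size)
        label, _ = classify_ca_regime(peaks)
        assert label == "bursting"

    def test_small_jitter_stays_periodic(self):
        rng = np.random.default_rng(1)
        peaks = 0.5 + rng.normal(0.0, 0.001, 30)
        assert classify_ca_regime(peaks)[0] == "periodic"
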