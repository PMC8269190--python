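import numpy as np
import pytest

from caslice import synth
from caslice.io import PacingProtocol, RecordingError
from caslice.transients import (
    NormalizedTrace,
    detect_paced_transients,
    fit_decay,
    normalize,
    quantify_recording,
    smooth,
)


class TestNormalize:
    def test_min_method(self):
        nt = normalize(np.array([100.0, 150.0, 100.0]))
        np.testing.assert_allclose(nt.f_over_f0, [1.0, 1.5, 1.0])
        assert nt.f0_value == 100.0

    def test_constant_trace(self):
        nt = normalize(np.array([5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(nt.f_over_f0, [1.0, 1.0, 1.0])

    def test_median_percentile_matches_hand_value(self):
        # median of (100, 150, 100) is 100, same F0 as "min" here
        nt = normalize(np.array([100.0, 150.0, 100.0]), "percentile:50")
        assert nt.f0_value == 100.0
        np.testing.assert_allclose(nt.f_over_f0, [1.0, 1.5, 1.0])

    def test_min_method_output_minimum_exactly_one(self):
        rng = np.random.default_rng(0)
        nt = normalize(rng.uniform(50, 200, 500))
        assert nt.f_over_f0.min() == 1.0

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(RecordingError, match="baseline"):
            normalize(np.array([-1.0, 5.0, 10.0]))

    def test_nonfinite_rejected(self):
        with pytest.raises(RecordingError, match="finite"):
            normalize(np.array([1.0, np.nan, 2.0]))

    def test_unknown_method_rejected(self):
        with pytest.raises(RecordingError, match="f0_method"):
            normalize(np.array([1.0, 2.0]), "mode")


class TestSmooth:
    def test_width_one_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(smooth(x, 1), x)

    def test_even_width_rejected(self):
        with pytest.raises(RecordingError, match="odd"):
            smooth(np.arange(10.0), 4)

    def test_constant_preserved(self):
        np.testing.assert_allclose(smooth(np.full(20, 3.0), 5), np.full(20, 3.0))


def _exp_trace(tau=0.30, amp=1.0, dt=0.01, stim=0.5, total=3.0):
    times = np.arange(int(total / dt) + 1) * dt
    f = np.ones_like(times)
    mask = times > stim
    f[mask] += amp * np.exp(-(times[mask] - stim) / tau)
    return times, f


class TestDetectPacedTransients:
    def test_single_kernel_amplitude_recovery(self):
        cfg = synth.SimConfig(
            seed=0, n_rows=1, n_cols=1, duration_s=4.0, frame_interval_s=0.01,
            pacing_rate_hz=0.5, pacing_start_s=0.5, amplitude=1.0, noise_sd=0.0,
        )
        rec, gt = synth.simulate_slice_recording(cfg)
        _, per_cell = quantify_recording(rec, fit=False)
        trs = per_cell["c000"]
        assert len(trs) == 2
        for tr in trs:
            assert tr.amplitude == pytest.approx(1.0, rel=0.02)

    def test_zero_stimuli_empty(self):
        nt = normalize(np.full(200, 100.0), times=np.arange(200) * 0.01)
        assert detect_paced_transients(nt, PacingProtocol((), 1.0)) == []

    def test_flat_trace_all_below_floor(self):
        nt = normalize(np.full(400, 100.0), times=np.arange(400) * 0.01)
        proto = PacingProtocol((1.0, 2.0), 1.0)
        assert detect_paced_transients(nt, proto) == []

    def test_search_window_truncated_at_next_stimulus(self):
        times, f = _exp_trace(stim=1.0)
        nt = NormalizedTrace("x", times, f, 1.0, "min")
        proto = PacingProtocol((1.0, 1.1), rate_hz=10.0)
        trs = detect_paced_transients(nt, proto, search_window_s=0.5)
        assert all(tr.peak_time <= 1.1 or tr.stim_index == 1 for tr in trs)


class TestFitDecay:
    def test_pure_exponential_noiseless(self):
        times, f = _exp_trace(tau=0.30)
        nt = NormalizedTrace("x", times, f, 1.0, "min")
        proto = PacingProtocol((0.5,), 0.5)
        tr = detect_paced_transients(nt, proto, search_window_s=1.5)[0]
        tr = fit_decay(nt, tr, proto)
        assert tr.fit_flag == "ok"
        assert tr.decay_tau == pytest.approx(0.30, abs=1e-3)

    def test_noisy_monte_carlo_median_error(self):
        proto = PacingProtocol((0.5,), 0.5)
        errs = []
        for seed in range(30):
            times, f = _exp_trace(tau=0.30)
            rng = np.random.default_rng(seed)
            f = f + rng.normal(0, 0.05, f.size)
            nt = NormalizedTrace("x", times, f, 1.0, "min")
            # wide baseline window: with a single sparse beat the offset
            # anchor dominates the tau error budget
            trs = detect_paced_transients(
                nt, proto, search_window_s=1.5, baseline_window_s=0.4
            )
            tr = fit_decay(nt, trs[0], proto)
            if tr.decay_tau is not None:
                errs.append(abs(tr.decay_tau - 0.30) / 0.30)
        assert np.median(errs) < 0.05

    def test_constant_segment_no_fit(self):
        times = np.arange(300) * 0.01
        f = np.ones_like(times)
        f[(times > 0.5) & (times <= 0.6)] = 2.0  # plateau then drop, no decay
        nt = NormalizedTrace("x", times, f, 1.0, "min")
        proto = PacingProtocol((0.5,), 0.5)
        trs = detect_paced_transients(nt, proto, search_window_s=0.08)
        tr = fit_decay(nt, trs[0], proto, fit_end_rule="fixed:0.05")
        assert tr.fit_flag == "no-fit"
        assert tr.decay_tau is None


class TestGeneratorProperties:
    def test_noiseless_amplitudes_within_two_percent(self):
        cfg = synth.SimConfig(
            seed=3, n_rows=2, n_cols=3, duration_s=8.0, frame_interval_s=0.005,
            pacing_rate_hz=1.0, pacing_start_s=0.4, amplitude=1.0, noise_sd=0.0,
            decay_tau_s=0.2,
        )
        rec, gt = synth.simulate_slice_recording(cfg)
        _, per_cell = quantify_recording(rec, fit=False)
        for cell, trs in per_cell.items():
            truth = gt.transient_amplitudes[cell]
            for tr in trs:
                assert tr.amplitude == pytest.approx(truth[tr.stim_index], rel=0.02)

    def test_ne_increases_amplitude_and_accelerates_decay(self):
        base = dict(
            seed=4, n_rows=2, n_cols=2, duration_s=6.0, frame_interval_s=0.005,
            pacing_rate_hz=1.0, pacing_start_s=0.4, amplitude=1.0, noise_sd=0.0,
        )
        rec_off, _ = synth.simulate_slice_recording(synth.SimConfig(**base))
        rec_on, _ = synth.simulate_slice_recording(
            synth.SimConfig(**base, ne_applied=True)
        )
        def mean_amp_tau(rec):
            _, per_cell = quantify_recording(rec)
            amps = [t.amplitude for trs in per_cell.values() for t in trs]
            taus = [t.decay_tau for trs in per_cell.values() for t in trs
                    if t.decay_tau is not None]
            return np.mean(amps), np.mean(taus)
        a_off, tau_off = mean_amp_tau(rec_off)
        a_on, tau_on = mean_amp_tau(rec_on)
        assert a_on > a_off
        assert tau_on < tau_off
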