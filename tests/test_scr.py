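import numpy as np
import pytest

from caslice import synth
from caslice.io import PacingProtocol, RecordingError
from caslice.pipeline import run_pipeline
from caslice.scr import (
    ScrEvent,
    detect_scr,
    detect_scr_recording,
    estimate_basal_stats,
    pace_stop_latency,
    summarize_scr,
)
from caslice.transients import NormalizedTrace, Transient, quantify_recording

NO_STIM = PacingProtocol((), rate_hz=1.0)


def _flat_trace(n=1000, dt=0.01, level=1.0, noise=0.0, seed=0):
    times = np.arange(n) * dt
    f = np.full(n, level)
    if noise:
        f = f + np.random.default_rng(seed).normal(0, noise, n)
    return times, f


class TestBasalStats:
    def test_gaussian_diastole_recovered(self):
        times, f = _flat_trace(1000, noise=0.01, seed=1)
        nt = NormalizedTrace("x", times, f, 1.0, "min")
        st = estimate_basal_stats(nt, NO_STIM)
        assert st.mean == pytest.approx(1.0, abs=0.002)
        assert st.sd == pytest.approx(0.01, rel=0.20)

    def test_square_event_excluded_iteratively(self):
        times, f = _flat_trace(1000, noise=0.01, seed=2)
        clean = f.copy()
        f[(times >= 3.0) & (times < 4.0)] += 0.5  # one large square event
        nt = NormalizedTrace("x", times, f, 1.0, "min")
        nt_clean = NormalizedTrace("x", times, clean, 1.0, "min")
        sd_with = estimate_basal_stats(nt, NO_STIM).sd
        sd_clean = estimate_basal_stats(nt_clean, NO_STIM).sd
        assert sd_with == pytest.approx(sd_clean, rel=0.25)

    def test_constant_trace_degenerate(self):
        times, f = _flat_trace(100)
        nt = NormalizedTrace("x", times, f, 1.0, "min")
        st = estimate_basal_stats(nt, NO_STIM)
        assert st.sd == 0.0
        assert st.degenerate

    def test_too_few_samples_rejected(self):
        times, f = _flat_trace(10)
        nt = NormalizedTrace("x", times, f, 1.0, "min")
        with pytest.raises(RecordingError, match="diastolic samples"):
            estimate_basal_stats(nt, NO_STIM)


def _ref_transient(amplitude=1.0):
    return Transient(
        cell="x", stim_index=0, stim_time=-1.0, onset_time=-1.0, peak_time=-1.0,
        amplitude=amplitude, peak_f_over_f0=1.0 + amplitude, baseline=1.0,
    )


def _bump_trace(amp, t_on=2.0, t_off=2.9, n=1000, dt=0.01, noise=0.004, seed=3):
    times = np.arange(n) * dt
    f = 1.0 + np.random.default_rng(seed).normal(0, noise, n)
    f[(times >= t_on) & (times < t_off)] += amp
    return NormalizedTrace("x", times, f, 1.0, "min")


class TestDetectScr:
    def test_ten_percent_amplitude_rule(self):
        # reference transient amplitude 1.0: a 0.05 bump is excluded, a
        # 0.15 bump is included
        small = detect_scr(_bump_trace(0.05), [_ref_transient(1.0)], NO_STIM)[0]
        large = detect_scr(_bump_trace(0.15), [_ref_transient(1.0)], NO_STIM)[0]
        assert small == []
        assert len(large) == 1
        assert large[0].amplitude == pytest.approx(0.15, abs=0.02)

    def test_square_bump_duration_crossing_arithmetic(self):
        # noiseless: crossings land within one frame of the true edges
        events, _ = detect_scr(
            _bump_trace(0.5, 2.0, 2.9, noise=0.0), [_ref_transient(1.0)], NO_STIM
        )
        assert len(events) == 1
        assert events[0].duration == pytest.approx(0.9, abs=0.01)
        assert events[0].onset == pytest.approx(2.0, abs=0.01)

    def test_square_bump_duration_with_noise(self):
        events, _ = detect_scr(_bump_trace(0.5, 2.0, 2.9), [_ref_transient(1.0)], NO_STIM)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(0.9, abs=0.08)

    def test_scale_invariance(self):
        cfg = synth.SimConfig(
            seed=9, n_rows=2, n_cols=2, duration_s=30.0, frame_interval_s=0.01,
            pacing_rate_hz=2.0, pacing_start_s=0.3, stop_time_s=4.0,
            scr_rate_per_s=0.2, noise_sd=1.0,
        )
        rec, _ = synth.simulate_slice_recording(cfg)
        b1 = run_pipeline(rec)
        rec.fluor = rec.fluor * 3.0  # positive rescaling of raw F
        b2 = run_pipeline(rec)
        e1, e2 = b1["event_table"], b2["event_table"]
        assert len(e1) == len(e2)
        np.testing.assert_allclose(e1["onset_s"], e2["onset_s"], atol=1e-9)
        np.testing.assert_allclose(e1["amplitude"], e2["amplitude"], rtol=1e-6)

    def test_no_event_overlaps_stimulus_window(self):
        cfg = synth.SimConfig(
            seed=10, n_rows=3, n_cols=3, duration_s=60.0, frame_interval_s=0.01,
            pacing_rate_hz=1.0, pacing_start_s=0.4, scr_rate_per_s=0.3,
            scr_duration_mean_s=0.15, scr_duration_sd_s=0.02, noise_sd=1.0,
        )
        rec, _ = synth.simulate_slice_recording(cfg)
        b = run_pipeline(rec)
        # one-frame slack: onsets are sub-frame interpolated crossings
        w = 0.8 / rec.protocol.rate_hz - cfg.frame_interval_s
        for _, ev in b["event_table"].iterrows():
            for s in rec.protocol.stimulus_times:
                assert not (s <= ev.onset_s <= s + w)

    def test_false_positive_rate_on_event_free_noise(self):
        cfg = synth.SimConfig(
            seed=11, n_rows=3, n_cols=4, duration_s=60.0, frame_interval_s=0.01,
            pacing_rate_hz=2.0, pacing_start_s=0.3, stop_time_s=4.0,
            scr_rate_per_s=0.0, noise_sd=2.0,
        )
        rec, _ = synth.simulate_slice_recording(cfg)
        b = run_pipeline(rec)
        exposure = sum(b["exposures"].values())
        assert len(b["event_table"]) / exposure < 0.01

    def test_high_snr_precision_recall_perfect(self):
        cfg = synth.SimConfig(
            seed=11, n_rows=5, n_cols=8, duration_s=60.0, frame_interval_s=0.01,
            pacing_rate_hz=2.0, pacing_start_s=0.3, stop_time_s=6.0,
            scr_rate_per_s=0.1, scr_amplitude_frac=0.3, scr_duration_mean_s=0.3,
            scr_duration_sd_s=0.05, min_event_gap_s=1.0, noise_sd=1.0,
            transient_lockout_s=1.6,
        )
        rec, gt = synth.simulate_slice_recording(cfg)
        assert len(gt.scr_events) >= 100
        b = run_pipeline(rec)
        det = b["event_table"]
        tol = 2 * cfg.frame_interval_s + 1e-9
        by_cell = {c: det[det.cell == c]["onset_s"].to_numpy() for c in rec.cells}
        tp = sum(
            1 for e in gt.scr_events
            if by_cell[e.cell].size and np.abs(by_cell[e.cell] - e.onset).min() <= tol
        )
        assert tp == len(gt.scr_events)  # recall 1.0
        assert len(det) == len(gt.scr_events)  # precision 1.0


class TestSummarize:
    def test_rate_arithmetic(self):
        events = [ScrEvent("a", t, t + 0.1, 0.3, 0.2, 0) for t in (1.0, 2.0, 3.0)]
        s = summarize_scr(events, {"a": 7.5}, n_cells=1)
        assert s.per_cell.loc[0, "rate_per_s"] == pytest.approx(0.4)

    def test_no_events(self):
        s = summarize_scr([], {"a": 5.0, "b": 5.0}, n_cells=2)
        assert (s.per_cell["rate_per_s"] == 0).all()
        assert s.fraction_of_cells_active == 0.0

    def test_zero_exposure_rejected(self):
        with pytest.raises(RecordingError, match="exposure"):
            summarize_scr([], {"a": 0.0}, n_cells=1)

    @pytest.mark.parametrize("lam", [0.1, 0.4])
    def test_recovered_rate_unbiased(self, lam):
        rates = []
        for seed in range(5):
            cfg = synth.SimConfig(
                seed=seed, n_rows=4, n_cols=5, duration_s=60.0,
                frame_interval_s=0.01, pacing_rate_hz=2.0, pacing_start_s=0.3,
                stop_time_s=4.0, scr_rate_per_s=lam, scr_duration_mean_s=0.05,
                scr_duration_sd_s=0.008, rise_tau_s=0.01, noise_sd=1.0,
                transient_lockout_s=1.6,
            )
            rec, _ = synth.simulate_slice_recording(cfg)
            rates.append(run_pipeline(rec)["scr_summary"].mean_rate)
        assert np.mean(rates) == pytest.approx(lam, rel=0.12)


class TestPaceStop:
    def _events(self, onsets_by_cell):
        return [
            ScrEvent(c, t, t + 0.05, 0.3, 0.2, 0)
            for c, ts in onsets_by_cell.items()
            for t in ts
        ]

    def test_latency_subtraction(self):
        proto = PacingProtocol((9.0,), 2.0, stop_time=10.0)
        res = pace_stop_latency(
            self._events({"a": [13.0]}), proto, recording_end=30.0, cells=["a"]
        )
        row = res.per_cell.iloc[0]
        assert row.latency_s == pytest.approx(3.0)
        assert not row.censored

    def test_censoring(self):
        proto = PacingProtocol((9.0,), 2.0, stop_time=10.0)
        res = pace_stop_latency(
            self._events({"a": [5.0]}), proto, recording_end=30.0, cells=["a"]
        )
        row = res.per_cell.iloc[0]
        assert row.censored
        assert row.latency_s == pytest.approx(20.0)

    def test_stop_time_required(self):
        with pytest.raises(RecordingError, match="stop_time"):
            pace_stop_latency([], PacingProtocol((1.0,), 2.0), 30.0, ["a"])

    def test_exponential_latency_oracle(self):
        # first-event times drawn exponential(lambda): mean latency ~ 1/lambda
        rng = np.random.default_rng(42)
        lam, stop, end = 0.5, 10.0, 100.0
        onsets = {f"c{i}": [stop + rng.exponential(1 / lam)] for i in range(200)}
        proto = PacingProtocol((9.0,), 2.0, stop_time=stop)
        res = pace_stop_latency(self._events(onsets), proto, end, list(onsets))
        observed = res.per_cell.loc[~res.per_cell.censored, "latency_s"].mean()
        assert observed == pytest.approx(1 / lam, rel=0.10)


class TestDetectRecording:
    def test_fallback_reference_amplitude_used(self):
        # one cell with no accepted transients still gets events scored
        # against the recording-level mean amplitude
        cfg = synth.SimConfig(
            seed=12, n_rows=1, n_cols=2, duration_s=30.0, frame_interval_s=0.01,
            pacing_rate_hz=2.0, pacing_start_s=0.3, stop_time_s=3.0,
            scr_rate_per_s=0.2, noise_sd=1.0,
        )
        rec, _ = synth.simulate_slice_recording(cfg)
        norms, per_cell = quantify_recording(rec)
        per_cell[rec.cells[0]] = []  # simulate a cell with failed beats
        events, exposures = detect_scr_recording(norms, per_cell, rec.protocol)
        assert set(exposures) == set(rec.cells)
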