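import numpy as np
import pytest

from caslice import synth
from caslice.coupling import (
    coupling_report,
    neighbor_latencies,
    observed_neighbor_probability,
    poisson_null_probability,
)
from caslice.io import AdjacencyGraph, RecordingError
from caslice.pipeline import run_pipeline
from caslice.scr import ScrEvent


def _ev(cell, onset, duration=0.9):
    return ScrEvent(cell, onset, onset + 0.1, 0.3, duration, 0)


@pytest.fixture
def pair_adjacency():
    return AdjacencyGraph(cells=("a", "b"), edges=frozenset({("a", "b")}), rule="grid-rook")


class TestNeighborLatencies:
    def test_latency_within_window(self, pair_adjacency):
        recs = neighbor_latencies([_ev("a", 5.0), _ev("b", 5.4)], pair_adjacency)
        src = recs[0]
        assert src.cell == "a"
        assert src.latencies[0].latency_s == pytest.approx(0.4)
        assert src.latencies[0].within_window

    def test_outside_window_excluded(self, pair_adjacency):
        recs = neighbor_latencies([_ev("a", 5.0), _ev("b", 6.1)], pair_adjacency)
        assert recs[0].n_within == 0
        assert not recs[0].latencies[0].within_window

    def test_neighbor_without_events_no_record(self, pair_adjacency):
        recs = neighbor_latencies([_ev("a", 5.0)], pair_adjacency)
        assert recs[0].latencies == []

    def test_empty_adjacency_rejected(self):
        adj = AdjacencyGraph(cells=("a", "b"), edges=frozenset(), rule="grid-rook")
        with pytest.raises(RecordingError, match="empty adjacency"):
            neighbor_latencies([_ev("a", 1.0)], adj)

    def test_fixed_window_rule(self, pair_adjacency):
        recs = neighbor_latencies(
            [_ev("a", 5.0, duration=0.1), _ev("b", 5.4)],
            pair_adjacency,
            window_rule="fixed:0.9",
        )
        assert recs[0].window_s == 0.9
        assert recs[0].n_within == 1

    def test_first_in_field_mode(self, pair_adjacency):
        events = [_ev("a", 3.0), _ev("b", 7.0), _ev("a", 7.2)]
        recs = neighbor_latencies(
            events, pair_adjacency, mode="first-in-field", stop_time=5.0
        )
        assert len(recs) == 1
        assert recs[0].cell == "b" and recs[0].onset == 7.0

    def test_claiming_unique_but_within_shared(self):
        # two sources adjacent to the same neighbor: both see the onset
        # within-window, only the earlier claims it
        adj = AdjacencyGraph(
            cells=("a", "b", "n"),
            edges=frozenset({("a", "n"), ("b", "n")}),
            rule="grid-rook",
        )
        recs = neighbor_latencies(
            [_ev("a", 5.0), _ev("b", 5.1), _ev("n", 5.5)], adj
        )
        by_cell = {r.cell: r for r in recs}
        assert by_cell["a"].n_within == 1 and by_cell["a"].n_claimed == 1
        assert by_cell["b"].n_within == 1 and by_cell["b"].n_claimed == 0


class TestObservedProbability:
    def test_single_hit(self, pair_adjacency):
        recs = neighbor_latencies([_ev("a", 5.0), _ev("b", 5.4)], pair_adjacency,
                                  recording_end=30.0)
        p, ci, n = observed_neighbor_probability(recs)
        assert p == pytest.approx(1.0) or p == pytest.approx(0.5)

    def test_no_hits_zero(self, pair_adjacency):
        events = [_ev("a", float(t)) for t in range(0, 20, 2)]
        recs = neighbor_latencies(events, pair_adjacency, recording_end=100.0)
        p, _, n = observed_neighbor_probability(recs)
        assert p == 0.0
        assert n == len(events)

    def test_zero_sources_rejected(self):
        with pytest.raises(RecordingError, match="source"):
            observed_neighbor_probability([])


class TestPoissonNull:
    def test_zero_rate(self):
        assert poisson_null_probability(0.0, 0.9, 3) == 0.0

    def test_saturation(self):
        assert poisson_null_probability(100.0, 1.0, 1) == pytest.approx(1.0)

    def test_printed_inputs_closed_form(self):
        # 1 - exp(-0.4 * 0.915) = 0.306529...
        p = poisson_null_probability(0.4, 0.915, 1)
        assert p == pytest.approx(1.0 - np.exp(-0.366))
        assert p == pytest.approx(0.30653, abs=5e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(RecordingError):
            poisson_null_probability(-0.1, 0.9, 1)
        with pytest.raises(RecordingError):
            poisson_null_probability(0.1, -0.9, 1)

    def test_monte_carlo_cross_check(self):
        # independent oracle: exponential-gap Poisson trains, window occupancy
        rng = np.random.default_rng(0)
        lam, w, trials = 0.4, 0.915, 40000
        hits = 0
        for _ in range(trials):
            t, hit = 0.0, False
            while t < w:
                t += rng.exponential(1 / lam)
                if t < w:
                    hit = True
                    break
            hits += hit
        mc = hits / trials
        assert poisson_null_probability(lam, w, 1) == pytest.approx(mc, abs=0.01)


class TestCouplingReport:
    def test_relabeling_invariance(self):
        rec, _ = synth.make_fixture("coupling_null")
        b = run_pipeline(rec)
        c1 = b["coupling"]
        # permute cell identities consistently in events and adjacency
        perm = {c: f"z{i:03d}" for i, c in enumerate(reversed(rec.cells))}
        events = [
            ScrEvent(perm[e.cell], e.onset, e.peak_time, e.amplitude, e.duration,
                     e.interval_index)
            for e in b["scr_events"]
        ]
        adj = b["adjacency"]
        adj2 = AdjacencyGraph(
            cells=tuple(perm[c] for c in adj.cells),
            edges=frozenset(tuple(sorted((perm[a], perm[b_]))) for a, b_ in adj.edges),
            rule=adj.rule,
        )
        exposures = {perm[c]: v for c, v in b["exposures"].items()}
        c2 = coupling_report(
            events, adj2, exposures,
            stop_time=rec.protocol.stop_time, recording_end=float(rec.times[-1]),
        )
        assert c2.p_obs == pytest.approx(c1.p_obs)
        assert c2.p_null == pytest.approx(c1.p_null)

    def test_latencies_nonnegative(self):
        rec, _ = synth.make_fixture("coupling_null")
        b = run_pipeline(rec)
        for src in b["coupling"].sources:
            for lr in src.latencies:
                assert lr.latency_s >= 0

    def test_monotone_in_k(self):
        # generator-level: fraction of true SCRs born inside a neighbor's
        # ongoing event is non-decreasing in the hazard multiplier
        fracs = []
        for k in (1.0, 5.0, 20.0):
            cfg = synth.SimConfig(
                seed=77, n_rows=5, n_cols=5, duration_s=40.0, frame_interval_s=0.01,
                pacing_rate_hz=2.0, pacing_start_s=0.3, stop_time_s=4.0,
                scr_rate_per_s=0.2, scr_duration_mean_s=0.5, scr_duration_sd_s=0.05,
                coupling_k=k, min_event_gap_s=3.0, noise_sd=1.0,
            )
            _, gt = synth.simulate_slice_recording(cfg)
            fracs.append(np.mean([e.coupled for e in gt.scr_events]))
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > fracs[0]

    def test_group_contrast_direction(self):
        # coupling only in one group: that group has the shortest mean
        # neighbor latency
        lat = {}
        for label, k in (("coupled", 20.0), ("uncoupled", 1.0)):
            cfg = synth.SimConfig(
                seed=5, n_rows=6, n_cols=6, duration_s=40.0, frame_interval_s=0.01,
                pacing_rate_hz=2.0, pacing_start_s=0.3, stop_time_s=4.0,
                scr_rate_per_s=0.3, scr_duration_mean_s=0.9, scr_duration_sd_s=0.05,
                coupling_k=k, min_event_gap_s=6.0, noise_sd=1.0,
            )
            rec, _ = synth.simulate_slice_recording(cfg)
            c = run_pipeline(rec)["coupling"]
            lat[label] = c.mean_neighbor_latency_s
        assert lat["coupled"] < lat["uncoupled"]
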