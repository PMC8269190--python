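"""Intercellular SCR synchronization vs an independent-events Poisson null.

For every source event, the analysis asks whether any adjacent cell fires
a new SCR within a coupling window W (by default the source event's own
duration).  The observed probability is compared with the closed-form
probability that independent homogeneous Poisson neighbors would do so:
``p_null = 1 - exp(-n_neighbors * lambda * W)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .io import AdjacencyGraph, RecordingError
from .scr import ScrEvent


@dataclass
class LatencyRecord:
    source_cell: str
    source_onset: float
    window_s: float
    neighbor_cell: str
    neighbor_onset: float
    latency_s: float
    within_window: bool
    claimed: bool = False  # attributed to this source as its secondary


@dataclass
class SourceRecord:
    cell: str
    onset: float
    window_s: float
    n_neighbors: int
    n_within: int  # neighbors with >= 1 onset inside the window
    n_claimed: int  # secondaries attributed to this source (no double counting)
    window_complete: bool  # False when the window runs past the recording end
    latencies: list[LatencyRecord] = field(default_factory=list)


@dataclass
class CouplingResult:
    window_rule: str
    p_obs: float
    p_obs_ci95: tuple[float, float]
    p_null: float
    p_null_loo: float | None
    lambda_hat: float
    lambda_hat_loo: float | None
    mean_window_s: float
    mean_n_neighbors: float
    n_source_events: int
    mean_neighbor_latency_s: float | None
    p_obs_per_pair: float
    sources: list[SourceRecord] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "window_rule": self.window_rule,
            "p_obs": self.p_obs,
            "p_obs_ci95": list(self.p_obs_ci95),
            "p_null": self.p_null,
            "p_null_formula": "1 - exp(-n_neighbors * lambda_hat * W)",
            "p_null_loo": self.p_null_loo,
            "lambda_hat": self.lambda_hat,
            "lambda_hat_loo": self.lambda_hat_loo,
            "mean_window_s": self.mean_window_s,
            "mean_n_neighbors": self.mean_n_neighbors,
            "n_source_events": self.n_source_events,
            "mean_neighbor_latency_s": self.mean_neighbor_latency_s,
            "p_obs_per_pair": self.p_obs_per_pair,
        }


def _window_length(window_rule: str, event: ScrEvent) -> float:
    if window_rule == "per-event-duration":
        return event.duration
    if window_rule.startswith("fixed:"):
        return float(window_rule.split(":", 1)[1])
    raise RecordingError(f"unknown window_rule {window_rule!r}")


def neighbor_latencies(
    events: list[ScrEvent],
    adjacency: AdjacencyGraph,
    window_rule: str = "per-event-duration",
    mode: str = "all",
    stop_time: float | None = None,
    recording_end: float | None = None,
) -> list[SourceRecord]:
    """Latency from each source event to its neighbors' next SCR onsets.

    ``mode="all"`` treats every event as a source; ``mode="first-in-field"``
    uses only the earliest post-stop event (ties broken by cell id).
    ``within_window`` (and hence p_obs) counts every neighbor onset inside
    the window, while ``claimed`` attributes each neighbor event to its
    earliest eligible source exactly once — the de-duplicated count feeds
    the leave-one-out null.  Sources whose window extends past
    *recording_end* are marked incomplete and excluded from probability
    estimates.
    """
    if not adjacency.edges and len(adjacency.cells) > 1:
        raise RecordingError("empty adjacency graph")
    events_sorted = sorted(events, key=lambda e: (e.onset, e.cell))
    by_cell: dict[str, list[ScrEvent]] = {}
    for ev in events_sorted:
        by_cell.setdefault(ev.cell, []).append(ev)

    if mode == "first-in-field":
        pool = [e for e in events_sorted if stop_time is None or e.onset > stop_time]
        sources = pool[:1]
    elif mode == "all":
        sources = events_sorted
    else:
        raise RecordingError(f"unknown source mode {mode!r}")

    claimed: set[tuple[str, float]] = set()
    records: list[SourceRecord] = []
    for src in sources:
        w = _window_length(window_rule, src)
        neighbors = adjacency.neighbors(src.cell)
        complete = recording_end is None or src.onset + w <= recording_end
        rec = SourceRecord(
            cell=src.cell, onset=src.onset, window_s=w,
            n_neighbors=len(neighbors), n_within=0, n_claimed=0,
            window_complete=complete,
        )
        for nb in neighbors:
            nxt = None
            for ev in by_cell.get(nb, []):
                if ev.onset >= src.onset and ev is not src:
                    nxt = ev
                    break
            if nxt is None:
                continue
            latency = nxt.onset - src.onset
            within = latency <= w
            claim = within and (nb, nxt.onset) not in claimed
            if within:
                rec.n_within += 1
            if claim:
                claimed.add((nb, nxt.onset))
                rec.n_claimed += 1
            rec.latencies.append(
                LatencyRecord(
                    source_cell=src.cell, source_onset=src.onset, window_s=w,
                    neighbor_cell=nb, neighbor_onset=nxt.onset,
                    latency_s=latency, within_window=within, claimed=claim,
                )
            )
        records.append(rec)
    return records


def _wilson_ci(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def observed_neighbor_probability(
    records: list[SourceRecord],
) -> tuple[float, tuple[float, float], int]:
    """Fraction of (complete-window) source events with >= 1 neighbor SCR
    onset inside the window; returns (p_obs, Wilson 95% CI, n used)."""
    usable = [r for r in records if r.window_complete]
    if not usable:
        raise RecordingError("no source events with a complete coupling window")
    k = sum(1 for r in usable if r.n_within >= 1)
    n = len(usable)
    return k / n, _wilson_ci(k, n), n


def poisson_null_probability(lambda_hat: float, window_s: float, n_neighbors: float) -> float:
    """P(>= 1 of n independent Poisson(lambda) neighbors fires within W)."""
    if lambda_hat < 0 or window_s <= 0 or n_neighbors < 1:
        raise RecordingError(
            "poisson_null_probability needs lambda >= 0, W > 0, n_neighbors >= 1"
        )
    return 1.0 - float(np.exp(-n_neighbors * lambda_hat * window_s))


def coupling_report(
    events: list[ScrEvent],
    adjacency: AdjacencyGraph,
    exposures: dict[str, float],
    window_rule: str = "per-event-duration",
    mode: str = "all",
    stop_time: float | None = None,
    recording_end: float | None = None,
) -> CouplingResult:
    """Full synchronization report: latencies, p_obs, Poisson null.

    ``lambda_hat`` is the pooled event rate over diastolic exposure; the
    leave-one-out variant re-estimates it excluding within-window
    secondary events (they are the very signal being tested, so a
    coupled recording inflates the naive null).
    """
    if not events:
        raise RecordingError("coupling_report requires at least one event")
    records = neighbor_latencies(
        events, adjacency, window_rule, mode, stop_time, recording_end
    )
    p_obs, ci, n_used = observed_neighbor_probability(records)

    total_exposure = float(sum(exposures.values()))
    if total_exposure <= 0:
        raise RecordingError("zero total diastolic exposure")
    lambda_hat = len(events) / total_exposure

    usable = [r for r in records if r.window_complete]
    mean_w = float(np.mean([r.window_s for r in usable]))
    mean_deg = float(np.mean([r.n_neighbors for r in usable]))
    p_null = poisson_null_probability(lambda_hat, mean_w, max(mean_deg, 1.0))

    n_secondary = sum(r.n_claimed for r in usable)
    lambda_loo = max(len(events) - n_secondary, 0) / total_exposure
    p_null_loo = poisson_null_probability(lambda_loo, mean_w, max(mean_deg, 1.0))

    within = [
        lr.latency_s for r in usable for lr in r.latencies if lr.within_window
    ]
    n_pairs = sum(r.n_neighbors for r in usable)
    n_within_total = sum(r.n_within for r in usable)
    return CouplingResult(
        window_rule=window_rule,
        p_obs=p_obs,
        p_obs_ci95=ci,
        p_null=p_null,
        p_null_loo=p_null_loo,
        lambda_hat=lambda_hat,
        lambda_hat_loo=lambda_loo,
        mean_window_s=mean_w,
        mean_n_neighbors=mean_deg,
        n_source_events=n_used,
        mean_neighbor_latency_s=float(np.mean(within)) if within else None,
        p_obs_per_pair=(n_within_total / n_pairs) if n_pairs else 0.0,
        sources=records,
    )


def latencies_to_frame(records: list[SourceRecord]) -> pd.DataFrame:
    cols = [
        "source_cell", "source_onset_s", "window_s", "neighbor_cell",
        "neighbor_onset_s", "latency_s", "within_window",
    ]
    rows = [
        {
            "source_cell": lr.source_cell,
            "source_onset_s": lr.source_onset,
            "window_s": lr.window_s,
            "neighbor_cell": lr.neighbor_cell,
            "neighbor_onset_s": lr.neighbor_onset,
            "latency_s": lr.latency_s,
            "within_window": lr.within_window,
        }
        for r in records
        for lr in r.latencies
    ]
    return pd.DataFrame(rows, columns=cols)
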