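"""End-to-end orchestration and group-level statistical reporting."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import alternans as alt_mod
from . import coupling as coup_mod
from . import io as io_mod
from . import scr as scr_mod
from . import transients as tr_mod
from .io import AdjacencyGraph, Recording, RecordingError

log = logging.getLogger(__name__)

#: provenance of every numeric default: a threshold either comes straight
#: from the published analysis rules or is an implementation default.
CONFIG_PROVENANCE = {
    "threshold_frac": "published rule: event amplitude >= 10% of triggered transient",
    "diff_frac": "published rule: consecutive amplitudes differ by >= 10%",
    "min_run": "published rule: alternation sustained >= 10 transients",
    "basal_sd_multiplier": "published rule: events bounded by 2 SD of basal fluorescence",
    "merge_gap_s": "implementation default",
    "smoothing_width": "implementation default",
    "search_window_s": "implementation default (0.8 / pacing rate when unset)",
    "baseline_window_s": "implementation default",
    "amplitude_floor": "implementation default",
    "window_rule": "default window = event duration (~0.9 s typical)",
    "adjacency_rule": "implementation default (the source never defines 'neighboring')",
    "adjacency_threshold_um": "implementation default (1.5 x median diameter when unset)",
    "f0_method": "published rule: F0 = minimum fluorescence of the same cell",
    "seed": "implementation default",
}


@dataclass
class AnalysisConfig:
    """All thresholds of the pipeline, defaults matching the published rules."""

    threshold_frac: float = 0.10
    diff_frac: float = 0.10
    min_run: int = 10
    basal_sd_multiplier: float = 2.0
    merge_gap_s: float = 0.05
    smoothing_width: int = 1
    search_window_s: float | None = None
    baseline_window_s: float = 0.05
    amplitude_floor: float = 0.05
    window_rule: str = "per-event-duration"
    adjacency_rule: str = "grid-rook"
    adjacency_threshold_um: float | None = None
    f0_method: str = "min"
    alternans_denominator: str = "max"
    seed: int = 0
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("threshold_frac", "diff_frac", "basal_sd_multiplier",
                     "merge_gap_s", "baseline_window_s"):
            if getattr(self, name) <= 0:
                raise RecordingError(f"{name} must be positive")
        if self.min_run < 2:
            raise RecordingError("min_run must be >= 2 transients")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def describe(self) -> pd.DataFrame:
        rows = []
        for f in dataclasses.fields(self):
            rows.append(
                {
                    "parameter": f.name,
                    "value": getattr(self, f.name),
                    "provenance": CONFIG_PROVENANCE.get(f.name, "implementation default"),
                }
            )
        return pd.DataFrame(rows)


def _adjacency_for(rec: Recording, config: AnalysisConfig) -> AdjacencyGraph | None:
    if rec.geometry is None:
        return None
    rule = config.adjacency_rule
    if rule == "grid-rook" and not rec.geometry.has_grid:
        rule = "centroid-distance"
    if rule == "grid-rook":
        return io_mod.adjacency_from_geometry(rec.geometry, rule="grid-rook")
    threshold = config.adjacency_threshold_um
    if threshold is None:
        threshold = io_mod.default_distance_threshold(rec.geometry)
    return io_mod.adjacency_from_geometry(
        rec.geometry, rule="centroid-distance", threshold_um=threshold
    )


def run_pipeline(
    recording: Recording,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """normalize -> transients -> SCR -> alternans -> (pace-stop) -> coupling.

    Returns a result bundle of typed objects and tables; writes CSV tables
    plus a manifest when *out_dir* is given.
    """
    config = config or AnalysisConfig()
    norms, per_cell = tr_mod.quantify_recording(
        recording,
        f0_method=config.f0_method,
        search_window_s=config.search_window_s,
        baseline_window_s=config.baseline_window_s,
        amplitude_floor=config.amplitude_floor,
        smoothing_width=config.smoothing_width,
    )
    n_transients = sum(len(v) for v in per_cell.values())
    log.info("stage transients: %d cells, %d transients", recording.n_cells, n_transients)

    events, exposures = scr_mod.detect_scr_recording(
        norms,
        per_cell,
        recording.protocol,
        threshold_frac=config.threshold_frac,
        sd_multiplier=config.basal_sd_multiplier,
        merge_gap_s=config.merge_gap_s,
        search_window_s=config.search_window_s,
    )
    summary = scr_mod.summarize_scr(events, exposures, recording.n_cells)
    log.info("stage scr: %d events, mean rate %.4g /s/cell",
             len(events), summary.mean_rate)

    calls = [
        alt_mod.classify_alternans(
            per_cell[c],
            diff_frac=config.diff_frac,
            min_run=config.min_run,
            denominator=config.alternans_denominator,
        )
        for c in recording.cells
        if per_cell[c]
    ]
    log.info("stage alternans: %d/%d cells positive",
             sum(c.positive for c in calls), len(calls))

    bundle: dict[str, Any] = {
        "normalized": norms,
        "transients": per_cell,
        "transient_table": tr_mod.transients_to_frame(per_cell),
        "scr_events": events,
        "event_table": scr_mod.events_to_frame(events),
        "exposures": exposures,
        "scr_summary": summary,
        "alternans_calls": calls,
        "alternans_table": alt_mod.calls_to_frame(calls),
        "config": config,
    }

    if recording.protocol.stop_time is not None:
        bundle["pace_stop"] = scr_mod.pace_stop_latency(
            events, recording.protocol, float(recording.times[-1]), recording.cells
        )

    adjacency = _adjacency_for(recording, config)
    if adjacency is not None and events:
        bundle["adjacency"] = adjacency
        bundle["coupling"] = coup_mod.coupling_report(
            events,
            adjacency,
            exposures,
            window_rule=config.window_rule,
            stop_time=recording.protocol.stop_time,
            recording_end=float(recording.times[-1]),
        )
        log.info("stage coupling: p_obs=%.3f p_null=%.3f",
                 bundle["coupling"].p_obs, bundle["coupling"].p_null)

    if out_dir is not None:
        tables: dict[str, Any] = {
            "transients": bundle["transient_table"],
            "events": bundle["event_table"],
            "calls": bundle["alternans_table"],
            "scr_summary": summary.per_cell,
        }
        if "pace_stop" in bundle:
            tables["pace_stop"] = bundle["pace_stop"].per_cell
        if "coupling" in bundle:
            tables["coupling_latencies"] = coup_mod.latencies_to_frame(
                bundle["coupling"].sources
            )
            tables["coupling_summary"] = pd.DataFrame(
                [bundle["coupling"].to_dict()]
            ).drop(columns=["p_obs_ci95"]).assign(
                p_obs_ci_lo=bundle["coupling"].p_obs_ci95[0],
                p_obs_ci_hi=bundle["coupling"].p_obs_ci95[1],
            )
        bundle["manifest"] = io_mod.write_results(
            tables, out_dir, config=config.to_dict(), seed=config.seed
        )
    return bundle


@dataclass
class GroupComparison:
    metric: str
    groups: dict[str, dict[str, float]]  # label -> {mean, sd, n}
    test: str  # "Welch" | "t" | "anova"
    statistic: float
    p_value: float
    normality: dict[str, float]  # label -> Shapiro-Wilk p


def compare_groups(
    values_by_group: Mapping[str, np.ndarray | list[float]],
    metric: str = "",
    test: str | None = None,
) -> GroupComparison:
    """Two-group Welch (default) or one-way ANOVA for 3+ groups.

    Group means are reported as mean +/- SD; a Shapiro-Wilk normality
    check (alpha 0.05) is recorded for each group but does not silently
    change the chosen test.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise RecordingError("compare_groups needs at least two groups")
    for k, v in groups.items():
        if v.size < 3:
            raise RecordingError(f"group {k!r} has {v.size} values (need >= 3)")
    normality = {}
    for k, v in groups.items():
        if np.ptp(v) == 0:
            normality[k] = float("nan")
        else:
            normality[k] = float(stats.shapiro(v).pvalue)
    samples = list(groups.values())
    if test is None:
        test = "Welch" if len(groups) == 2 else "anova"
    if test == "Welch":
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "t":
        res = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "anova":
        res = stats.f_oneway(*samples)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise RecordingError(f"unknown test {test!r}")
    if np.isnan(statistic):  # identical groups with zero variance
        statistic, p = 0.0, 1.0
    return GroupComparison(
        metric=metric,
        groups={
            k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(v.size)}
            for k, v in groups.items()
        },
        test=test,
        statistic=statistic,
        p_value=p,
        normality=normality,
    )
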