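"""Diastolic spontaneous Ca2+ release (SCR) detection, rates and latencies.

An SCR candidate is a contiguous diastolic region whose F/F0 exceeds
basal mean + 2 basal SD; it is kept iff its baseline-subtracted amplitude
is at least ``threshold_frac`` (default 10%) of the cell's mean accepted
paced-transient amplitude.  All thresholds are relative, so detection is
invariant to multiplying raw fluorescence by a positive constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PacingProtocol, RecordingError
from .transients import NormalizedTrace, Transient, default_search_window

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRAC = 0.10
DEFAULT_SD_MULTIPLIER = 2.0
DEFAULT_MERGE_GAP_S = 0.05
MIN_BASAL_SAMPLES = 20


@dataclass
class ScrEvent:
    """One diastolic release event in one cell."""

    cell: str
    onset: float  # first upward threshold crossing (s)
    peak_time: float
    amplitude: float  # delta F/F0 above diastolic basal mean
    duration: float  # time between bounding threshold crossings (s)
    interval_index: int


@dataclass
class BasalStats:
    mean: float
    sd: float
    n_kept: int
    n_total: int
    degenerate: bool = False  # SD == 0; threshold fell back to amplitude rule


@dataclass
class ScrSummary:
    per_cell: pd.DataFrame  # cell, n_events, exposure_s, rate_per_s
    fraction_of_cells_active: float
    n_cells: int

    @property
    def mean_rate(self) -> float:
        return float(self.per_cell["rate_per_s"].mean())


@dataclass
class PaceStopResult:
    per_cell: pd.DataFrame  # cell, latency_s, censored, censor_at_s
    stop_time: float


def diastolic_mask(
    times: np.ndarray,
    protocol: PacingProtocol,
    search_window_s: float | None = None,
) -> np.ndarray:
    """Boolean mask of frames outside every stimulus-locked transient window."""
    if search_window_s is None:
        search_window_s = default_search_window(protocol.rate_hz)
    mask = np.ones(times.shape, dtype=bool)
    for s in protocol.stimulus_times:
        mask &= ~((times >= s) & (times <= s + search_window_s))
    return mask


def estimate_basal_stats(
    norm_trace: NormalizedTrace,
    protocol: PacingProtocol,
    search_window_s: float | None = None,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    max_iter: int = 10,
) -> BasalStats:
    """Robust basal mean/SD from diastolic samples.

    Iteratively excludes samples more than ``sd_multiplier`` SDs from the
    running mean (at most *max_iter* passes) so that sparse events do not
    inflate the SD estimate.  The SD of a k-sigma-truncated sample is
    rescaled by the Gaussian truncation consistency factor, otherwise the
    iteration collapses to ~0.7 of the true noise SD and every downstream
    2-SD threshold is too tight.
    """
    from scipy.stats import norm

    k = sd_multiplier
    trunc_factor = float(
        np.sqrt(1.0 - 2.0 * k * norm.pdf(k) / (2.0 * norm.cdf(k) - 1.0))
    )
    mask = diastolic_mask(norm_trace.times, protocol, search_window_s)
    x = norm_trace.f_over_f0[mask]
    if x.size < MIN_BASAL_SAMPLES:
        raise RecordingError(
            f"cell {norm_trace.cell!r}: only {x.size} diastolic samples "
            f"(need >= {MIN_BASAL_SAMPLES})"
        )
    n_total = int(x.size)
    keep = np.ones(x.size, dtype=bool)
    truncated = False
    for _ in range(max_iter):
        mean = float(x[keep].mean())
        sd = float(x[keep].std())
        if truncated:
            sd /= trunc_factor
        if sd == 0.0:
            break
        new_keep = np.abs(x - mean) <= sd_multiplier * sd
        if new_keep.sum() < MIN_BASAL_SAMPLES or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        truncated = True
    mean = float(x[keep].mean())
    sd = float(x[keep].std())
    if truncated:
        sd /= trunc_factor
    return BasalStats(
        mean=mean, sd=sd, n_kept=int(keep.sum()), n_total=n_total,
        degenerate=(sd == 0.0),
    )


def _diastolic_intervals(
    norm_trace: NormalizedTrace,
    transients: list[Transient],
    protocol: PacingProtocol,
    threshold: float,
    search_window_s: float,
) -> list[tuple[float, float]]:
    """Per-cycle diastolic intervals.

    Each interval runs from the first return of F/F0 below *threshold*
    after the paced peak to the next stimulus; after the last stimulus
    (pace-stop or end of train) the whole tail past the final transient's
    return is diastolic.
    """
    t = norm_trace.times
    f = norm_trace.f_over_f0
    stims = list(protocol.stimulus_times)
    peak_by_stim: dict[int, float] = {tr.stim_index: tr.peak_time for tr in transients}
    intervals: list[tuple[float, float]] = []
    if not stims:
        return [(float(t[0]), float(t[-1]))]
    if t[0] < stims[0]:  # unpaced lead-in is diastole too
        intervals.append((float(t[0]), float(stims[0])))
    for i, s in enumerate(stims):
        next_s = stims[i + 1] if i + 1 < len(stims) else float(t[-1])
        peak_t = peak_by_stim.get(i)
        if peak_t is None:
            # failed beat: fall back to the fixed transient window
            start = s + search_window_s
        else:
            after = (t > peak_t) & (t <= next_s)
            below = after & (f < threshold)
            if below.any():
                start = float(t[np.flatnonzero(below)[0]])
            else:
                start = next_s  # never returned to baseline: no diastole
        if start < next_s:
            intervals.append((start, float(next_s)))
    return intervals


def detect_scr(
    norm_trace: NormalizedTrace,
    transients: list[Transient],
    protocol: PacingProtocol,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
    search_window_s: float | None = None,
    basal: BasalStats | None = None,
    fallback_ref_amplitude: float | None = None,
) -> tuple[list[ScrEvent], float]:
    """Detect SCR events in one cell; returns (events, diastolic exposure s).

    The amplitude reference is the cell's mean accepted transient
    amplitude; when the cell has no accepted transients the caller may
    supply *fallback_ref_amplitude* (recording-level mean, flagged in the
    log).
    """
    if search_window_s is None:
        search_window_s = default_search_window(protocol.rate_hz)
    if basal is None:
        basal = estimate_basal_stats(
            norm_trace, protocol, search_window_s, sd_multiplier
        )
    if transients:
        ref_amp = float(np.mean([tr.amplitude for tr in transients]))
    elif fallback_ref_amplitude is not None:
        log.warning(
            "cell %s: no accepted transients; using recording-level reference "
            "amplitude %.4g", norm_trace.cell, fallback_ref_amplitude,
        )
        ref_amp = float(fallback_ref_amplitude)
    else:
        raise RecordingError(
            f"cell {norm_trace.cell!r}: no accepted transients and no fallback "
            f"reference amplitude"
        )
    min_amp = threshold_frac * ref_amp
    if basal.degenerate:
        # SD == 0 (e.g. constant diastole): the 2-SD rule is vacuous, so the
        # region threshold falls back to the amplitude rule alone.
        threshold = basal.mean + min_amp
        log.warning(
            "cell %s: basal SD is 0; thresholding on amplitude rule only",
            norm_trace.cell,
        )
    else:
        threshold = basal.mean + sd_multiplier * basal.sd

    t = norm_trace.times
    f = norm_trace.f_over_f0
    intervals = _diastolic_intervals(
        norm_trace, transients, protocol, threshold, search_window_s
    )
    exposure = float(sum(b - a for a, b in intervals))
    events: list[ScrEvent] = []
    for k, (a, b) in enumerate(intervals):
        sel = np.flatnonzero((t >= a) & (t <= b))
        if sel.size < 2:
            continue
        above = f[sel] > threshold
        regions = _contiguous_regions(above)
        regions = _merge_regions(regions, t[sel], merge_gap_s)
        for lo, hi in regions:  # half-open frame slice [lo, hi)
            gi_lo, gi_hi = sel[lo], sel[hi - 1]
            amp = float(f[gi_lo:gi_hi + 1].max() - basal.mean)
            if amp < min_amp:
                continue
            peak_idx = gi_lo + int(np.argmax(f[gi_lo:gi_hi + 1]))
            # onset = the upward crossing that rises into the peak itself, so
            # a sub-threshold noise blip merged onto the front of the region
            # cannot drag the onset earlier
            j = peak_idx
            while j > gi_lo and f[j - 1] > threshold:
                j -= 1
            onset = _cross_time(t, f, j, threshold, up=True)
            t_off = _cross_time(t, f, gi_hi, threshold, up=False)
            events.append(
                ScrEvent(
                    cell=norm_trace.cell,
                    onset=onset,
                    peak_time=float(t[peak_idx]),
                    amplitude=amp,
                    duration=max(t_off - onset, float(t[1] - t[0])),
                    interval_index=k,
                )
            )
    return events, exposure


def _contiguous_regions(above: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) index runs where *above* is True."""
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_regions(
    regions: list[tuple[int, int]], t: np.ndarray, merge_gap_s: float
) -> list[tuple[int, int]]:
    if not regions:
        return regions
    merged = [regions[0]]
    for lo, hi in regions[1:]:
        plo, phi = merged[-1]
        if t[lo] - t[phi - 1] < merge_gap_s:
            merged[-1] = (plo, hi)
        else:
            merged.append((lo, hi))
    return merged


def _cross_time(t: np.ndarray, f: np.ndarray, idx: int, level: float, up: bool) -> float:
    """Linear-interpolated threshold crossing adjacent to frame *idx*."""
    if up:
        j = idx - 1
        if j < 0 or f[j] > level or f[idx] == f[j]:
            return float(t[idx])
        frac = (level - f[j]) / (f[idx] - f[j])
        return float(t[j] + frac * (t[idx] - t[j]))
    j = idx + 1
    if j >= len(t) or f[j] > level or f[idx] == f[j]:
        return float(t[idx])
    frac = (f[idx] - level) / (f[idx] - f[j])
    return float(t[idx] + frac * (t[j] - t[idx]))


def detect_scr_recording(
    norms: dict[str, NormalizedTrace],
    per_cell_transients: dict[str, list[Transient]],
    protocol: PacingProtocol,
    **kwargs,
) -> tuple[list[ScrEvent], dict[str, float]]:
    """Run :func:`detect_scr` for every cell of a recording."""
    all_amps = [
        tr.amplitude for trs in per_cell_transients.values() for tr in trs
    ]
    fallback = float(np.mean(all_amps)) if all_amps else None
    events: list[ScrEvent] = []
    exposures: dict[str, float] = {}
    for cell, nt in norms.items():
        evs, exp = detect_scr(
            nt,
            per_cell_transients.get(cell, []),
            protocol,
            fallback_ref_amplitude=fallback,
            **kwargs,
        )
        events.extend(evs)
        exposures[cell] = exp
    return events, exposures


def summarize_scr(
    events: list[ScrEvent],
    exposures: dict[str, float],
    n_cells: int | None = None,
) -> ScrSummary:
    """Per-cell SCR rates over diastolic exposure and fraction of active cells."""
    if n_cells is None:
        n_cells = len(exposures)
    rows = []
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.cell] = counts.get(ev.cell, 0) + 1
    for cell, exp in exposures.items():
        if exp <= 0:
            raise RecordingError(f"cell {cell!r}: zero diastolic exposure")
        n = counts.get(cell, 0)
        rows.append(
            {"cell": cell, "n_events": n, "exposure_s": exp, "rate_per_s": n / exp}
        )
    per_cell = pd.DataFrame(rows, columns=["cell", "n_events", "exposure_s", "rate_per_s"])
    n_active = int((per_cell["n_events"] > 0).sum())
    return ScrSummary(
        per_cell=per_cell,
        fraction_of_cells_active=n_active / n_cells if n_cells else 0.0,
        n_cells=n_cells,
    )


def pace_stop_latency(
    events: list[ScrEvent],
    protocol: PacingProtocol,
    recording_end: float,
    cells: list[str],
) -> PaceStopResult:
    """Latency from pacing stop to each cell's first SCR onset.

    Cells with no post-stop event are right-censored at
    (recording end - stop_time); events before stop_time are ignored.
    """
    if protocol.stop_time is None:
        raise RecordingError("pace_stop_latency requires a protocol with stop_time")
    stop = protocol.stop_time
    censor_at = recording_end - stop
    first: dict[str, float] = {}
    for ev in sorted(events, key=lambda e: e.onset):
        if ev.onset > stop and ev.cell not in first:
            first[ev.cell] = ev.onset - stop
    rows = [
        {
            "cell": c,
            "latency_s": first.get(c, censor_at),
            "censored": c not in first,
            "censor_at_s": censor_at,
        }
        for c in cells
    ]
    return PaceStopResult(
        per_cell=pd.DataFrame(rows, columns=["cell", "latency_s", "censored", "censor_at_s"]),
        stop_time=stop,
    )


def events_to_frame(events: list[ScrEvent]) -> pd.DataFrame:
    cols = ["cell", "onset_s", "peak_s", "amplitude", "duration_s", "interval_index"]
    rows = [
        {
            "cell": e.cell,
            "onset_s": e.onset,
            "peak_s": e.peak_time,
            "amplitude": e.amplitude,
            "duration_s": e.duration,
            "interval_index": e.interval_index,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=cols)
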