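"""F/F0 normalization and stimulus-locked Ca2+ transient quantification."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import PacingProtocol, Recording, RecordingError

log = logging.getLogger(__name__)

#: transients with baseline-subtracted amplitude at or below this are dropped
DEFAULT_AMPLITUDE_FLOOR = 0.05
DEFAULT_BASELINE_WINDOW_S = 0.05


@dataclass
class NormalizedTrace:
    """A single-cell trace expressed as F/F0.

    F0 is the cell's minimum fluorescence by default (``f0_method="min"``),
    so min(f_over_f0) == 1 exactly under that method.
    """

    cell: str
    times: np.ndarray
    f_over_f0: np.ndarray
    f0_value: float
    f0_method: str


@dataclass
class Transient:
    """One stimulus-locked transient.

    ``amplitude`` is baseline-subtracted peak (delta F/F0), where the
    baseline is the mean F/F0 just before the stimulus; ``peak_f_over_f0``
    carries the raw peak for callers who prefer un-subtracted values.
    """

    cell: str
    stim_index: int
    stim_time: float
    onset_time: float
    peak_time: float
    amplitude: float
    peak_f_over_f0: float
    baseline: float
    decay_tau: float | None = None
    fit_residual: float | None = None
    fit_flag: str = "unfit"
    fit_window: tuple[float, float] | None = None


def normalize(
    trace: np.ndarray,
    f0_method: str = "min",
    *,
    times: np.ndarray | None = None,
    cell: str = "",
) -> NormalizedTrace:
    """Normalize a raw fluorescence trace to F/F0.

    ``f0_method`` is ``"min"`` (the default) or ``"percentile:<p>"``.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.isfinite(trace).all():
        raise RecordingError(f"trace for cell {cell!r} contains non-finite values")
    if f0_method == "min":
        f0 = float(trace.min())
    elif f0_method.startswith("percentile:"):
        p = float(f0_method.split(":", 1)[1])
        f0 = float(np.percentile(trace, p))
    else:
        raise RecordingError(f"unknown f0_method {f0_method!r}")
    if f0 <= 0:
        raise RecordingError(
            f"non-physical baseline: F0={f0} for cell {cell!r} (must be > 0)"
        )
    if times is None:
        times = np.arange(trace.size, dtype=float)
    return NormalizedTrace(
        cell=cell,
        times=np.asarray(times, dtype=float),
        f_over_f0=trace / f0,
        f0_value=f0,
        f0_method=f0_method,
    )


def smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average of odd *width*; width 1 is the identity.

    Applied identically before all detectors when enabled, so thresholds
    stay comparable across modules.
    """
    if width <= 1:
        return values
    if width % 2 == 0:
        raise RecordingError("smoothing width must be odd")
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def default_search_window(rate_hz: float) -> float:
    return 0.8 / rate_hz


def detect_paced_transients(
    norm_trace: NormalizedTrace,
    protocol: PacingProtocol,
    search_window_s: float | None = None,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
    amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
) -> list[Transient]:
    """One transient candidate per stimulus.

    Peak = max F/F0 in (stim, stim + search_window], truncated at the next
    stimulus; baseline = mean F/F0 over [stim - baseline_window, stim).
    Candidates with amplitude <= *amplitude_floor* are dropped (failed
    beats), not returned.
    """
    if search_window_s is None:
        search_window_s = default_search_window(protocol.rate_hz)
    if search_window_s <= 0 or baseline_window_s <= 0:
        raise RecordingError("search and baseline windows must be positive")
    t = norm_trace.times
    f = norm_trace.f_over_f0
    stims = protocol.stimulus_times
    out: list[Transient] = []
    for i, s in enumerate(stims):
        w_end = s + search_window_s
        if i + 1 < len(stims) and stims[i + 1] < w_end:
            log.debug(
                "cell %s stim %d: search window truncated at next stimulus",
                norm_trace.cell, i,
            )
            w_end = stims[i + 1]
        in_win = (t > s) & (t <= w_end)
        if not in_win.any():
            continue
        idx = np.flatnonzero(in_win)
        peak_rel = int(np.argmax(f[idx]))
        peak_idx = idx[peak_rel]
        base_mask = (t >= s - baseline_window_s) & (t < s)
        baseline = float(f[base_mask].mean()) if base_mask.any() else float(
            f[np.searchsorted(t, s)]
        )
        amplitude = float(f[peak_idx] - baseline)
        if amplitude <= amplitude_floor:
            continue
        onset_level = baseline + 0.1 * amplitude
        onset_time = s
        for j in idx:
            if f[j] > onset_level:
                onset_time = float(t[j])
                break
            if j >= peak_idx:
                break
        out.append(
            Transient(
                cell=norm_trace.cell,
                stim_index=i,
                stim_time=float(s),
                onset_time=min(onset_time, float(t[peak_idx])),
                peak_time=float(t[peak_idx]),
                amplitude=amplitude,
                peak_f_over_f0=float(f[peak_idx]),
                baseline=baseline,
            )
        )
    return out


def _monoexp(t, a, tau, c):
    return c + a * np.exp(-t / tau)


def fit_decay(
    norm_trace: NormalizedTrace,
    transient: Transient,
    protocol: PacingProtocol,
    fit_end_rule: str = "auto",
    min_samples: int = 5,
) -> Transient:
    """Fit a monoexponential decay to one transient, in place.

    Window: [peak, min(next stimulus, first return to baseline + 10% of
    amplitude)].  Least-squares via ``scipy.optimize.curve_fit``; falls
    back to log-linear regression (flagged ``"loglin"``) when the
    nonlinear fit fails.  Windows with fewer than *min_samples* points or
    no decay get ``fit_flag="no-fit"`` and ``decay_tau=None``.
    """
    t = norm_trace.times
    f = norm_trace.f_over_f0
    tp = transient.peak_time
    stims = [s for s in protocol.stimulus_times if s > transient.stim_time]
    t_end = stims[0] if stims else float(t[-1])
    if fit_end_rule == "auto":
        return_level = transient.baseline + 0.1 * transient.amplitude
        idx = np.flatnonzero((t > tp) & (t <= t_end))
        below = f[idx] < return_level
        # sustained return (3 consecutive sub-level samples) so a single
        # noise dip cannot truncate the fit window early
        run = below & np.roll(below, -1) & np.roll(below, -2)
        if idx.size >= 3 and run[:-2].any():
            t_end = float(t[idx[np.flatnonzero(run[:-2])[0]]])
    elif fit_end_rule.startswith("fixed:"):
        t_end = min(t_end, tp + float(fit_end_rule.split(":", 1)[1]))
    else:
        raise RecordingError(f"unknown fit_end_rule {fit_end_rule!r}")

    mask = (t >= tp) & (t <= t_end)
    transient.fit_window = (float(tp), float(t_end))
    if mask.sum() < min_samples:
        transient.fit_flag = "no-fit"
        transient.decay_tau = None
        return transient
    ts = t[mask] - tp
    ys = f[mask]
    if ys[-1] >= ys[0]:
        transient.fit_flag = "no-fit"
        transient.decay_tau = None
        return transient
    a0 = max(ys[0] - ys[-1], 1e-9)
    tau0 = max((ts[-1] - ts[0]) / 3.0, 1e-6)
    c = transient.baseline  # offset anchored to the pre-stimulus baseline
    try:
        popt, _ = curve_fit(
            lambda t, a, tau: _monoexp(t, a, tau, c),
            ts,
            ys,
            p0=(a0, tau0),
            bounds=([0, 1e-6], [np.inf, np.inf]),
            maxfev=5000,
        )
        a, tau = popt
        resid = float(np.linalg.norm(ys - _monoexp(ts, a, tau, c)))
        transient.decay_tau = float(tau)
        transient.fit_residual = resid
        transient.fit_flag = "ok"
    except (RuntimeError, ValueError):
        # log-linear fallback on the baseline-subtracted positive part
        y = ys - transient.baseline
        keep = y > 0
        if keep.sum() < min_samples:
            transient.fit_flag = "no-fit"
            transient.decay_tau = None
            return transient
        slope, _ = np.polyfit(ts[keep], np.log(y[keep]), 1)
        if slope >= 0:
            transient.fit_flag = "no-fit"
            transient.decay_tau = None
            return transient
        transient.decay_tau = float(-1.0 / slope)
        transient.fit_residual = None
        transient.fit_flag = "loglin"
    return transient


def quantify_recording(
    rec: Recording,
    f0_method: str = "min",
    search_window_s: float | None = None,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
    amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
    smoothing_width: int = 1,
    fit: bool = True,
) -> tuple[dict[str, NormalizedTrace], dict[str, list[Transient]]]:
    """Normalize every cell and quantify its paced transients."""
    norms: dict[str, NormalizedTrace] = {}
    per_cell: dict[str, list[Transient]] = {}
    for i, cell in enumerate(rec.cells):
        raw = smooth(rec.fluor[i], smoothing_width)
        nt = normalize(raw, f0_method, times=rec.times, cell=cell)
        trs = detect_paced_transients(
            nt,
            rec.protocol,
            search_window_s=search_window_s,
            baseline_window_s=baseline_window_s,
            amplitude_floor=amplitude_floor,
        )
        if fit:
            for tr in trs:
                fit_decay(nt, tr, rec.protocol)
        norms[cell] = nt
        per_cell[cell] = trs
    return norms, per_cell


def transients_to_frame(per_cell: dict[str, list[Transient]]) -> pd.DataFrame:
    rows = []
    for cell, trs in per_cell.items():
        for tr in trs:
            rows.append(
                {
                    "cell": cell,
                    "stim_index": tr.stim_index,
                    "t_peak": tr.peak_time,
                    "amplitude": tr.amplitude,
                    "peak_f_over_f0": tr.peak_f_over_f0,
                    "tau": tr.decay_tau,
                    "fit_flag": tr.fit_flag,
                }
            )
    cols = ["cell", "stim_index", "t_peak", "amplitude", "peak_f_over_f0", "tau", "fit_flag"]
    return pd.DataFrame(rows, columns=cols)
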