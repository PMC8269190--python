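"""Line-scan kymograph wavefront detection and propagation-speed estimation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .io import RecordingError

MIN_POSITIONS = 8
MIN_LINES = 3
MIN_FRONT_POINTS = 3
#: a wave is declared present only when max - basal > this many basal SDs
WAVE_SNR_MULTIPLIER = 4.0


@dataclass
class Kymograph:
    """Position x time fluorescence matrix from line-scan acquisition."""

    values: np.ndarray  # [n_positions, n_lines]
    pixel_um: float
    line_interval_s: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RecordingError("kymograph must be a 2-D position x time matrix")
        if self.pixel_um <= 0 or self.line_interval_s <= 0:
            raise RecordingError("pixel_um and line_interval_s must be positive")
        npos, nlin = self.values.shape
        if npos < MIN_POSITIONS or nlin < MIN_LINES:
            raise RecordingError(
                f"kymograph too small: {npos} positions x {nlin} lines "
                f"(need >= {MIN_POSITIONS} x {MIN_LINES})"
            )

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.pixel_um

    @property
    def line_times_s(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.line_interval_s


@dataclass
class WaveFit:
    speed_um_s: float
    direction: int  # +1 toward increasing position, -1 decreasing
    intercept: float
    r_squared: float
    n_points: int
    front: pd.DataFrame  # columns: time_s, position_um
    method: str = "half-max"


def _basal_stats(values: np.ndarray) -> tuple[float, float]:
    """Basal level/SD from the lowest quartile of pixels (pre-front pool)."""
    flat = np.sort(values.ravel())
    lower = flat[: max(8, flat.size // 4)]
    return float(lower.mean()), float(lower.std())


def detect_wavefront(kymo: Kymograph, level: float = 0.5) -> pd.DataFrame:
    """Per-line sub-pixel front positions at the given fractional level.

    Threshold = basal + level * (max - basal).  For each usable line, the
    front is the crossing of that threshold scanning along the propagation
    direction, linearly interpolated between pixels.  Lines recorded
    before wave initiation or after full invasion are excluded.
    """
    v = kymo.values
    basal, basal_sd = _basal_stats(v)
    vmax = float(v.max())
    if not vmax - basal > WAVE_SNR_MULTIPLIER * basal_sd:
        raise RecordingError("no front: max - basal below 4x basal SD")
    threshold = basal + level * (vmax - basal)

    npos, nlin = v.shape
    # propagation direction: does the wave arrive first at low or high x?
    arrival = np.full(npos, np.nan)
    for p in range(npos):
        above = np.flatnonzero(v[p] >= threshold)
        if above.size:
            arrival[p] = above[0]
    ok = np.isfinite(arrival)
    if ok.sum() < MIN_FRONT_POINTS:
        raise RecordingError("no front: threshold crossed at fewer than 3 positions")
    slope = np.polyfit(np.flatnonzero(ok), arrival[ok], 1)[0]
    direction = 1 if slope >= 0 else -1

    rows = []
    for j in range(nlin):
        line = v[:, j] if direction == 1 else v[::-1, j]
        above = line >= threshold
        if not above[0] or above.all():
            continue  # pre-initiation (front not entered) or fully invaded
        k = int(np.argmin(above))  # first pixel below threshold
        f0, f1 = line[k - 1], line[k]
        frac = 0.0 if f0 == f1 else (f0 - threshold) / (f0 - f1)
        pos_px = (k - 1) + frac
        if direction == -1:
            pos_px = (npos - 1) - pos_px
        rows.append(
            {"time_s": j * kymo.line_interval_s, "position_um": pos_px * kymo.pixel_um}
        )
    if len(rows) < MIN_FRONT_POINTS:
        raise RecordingError(
            f"no front: threshold crossings on only {len(rows)} lines (need >= 3)"
        )
    return pd.DataFrame(rows, columns=["time_s", "position_um"])


def wave_speed(front: pd.DataFrame, method: str = "half-max") -> WaveFit:
    """Ordinary least-squares speed from (time, position) front points."""
    if len(front) < MIN_FRONT_POINTS:
        raise RecordingError("wave_speed requires at least 3 front points")
    t = front["time_s"].to_numpy(float)
    x = front["position_um"].to_numpy(float)
    if np.ptp(t) == 0:
        raise RecordingError("zero time spread in front points")
    res = stats.linregress(t, x)
    return WaveFit(
        speed_um_s=float(abs(res.slope)),
        direction=1 if res.slope >= 0 else -1,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(front),
        front=front,
        method=method,
    )


def estimate_wave_speed(kymo: Kymograph, level: float = 0.5) -> WaveFit:
    """Convenience: detect_wavefront + wave_speed."""
    return wave_speed(detect_wavefront(kymo, level))


def wave_speed_arrival(kymo: Kymograph, smooth_lines: int = 31) -> WaveFit:
    """Arrival-lag speed estimator for low-SNR kymographs.

    Each position row is box-smoothed along time and its half-range
    crossing time (sub-line interpolated) taken as the front arrival;
    speed is the OLS slope of position vs arrival time.  Robust when
    per-pixel noise defeats the spatial half-max detector.
    """
    kernel = np.ones(smooth_lines) / smooth_lines
    lags = np.full(kymo.values.shape[0], np.nan)
    for p, row in enumerate(kymo.values):
        s = np.convolve(row, kernel, mode="same")
        lo, hi = np.percentile(s, 5), np.percentile(s, 95)
        thr = 0.5 * (lo + hi)
        idx = np.flatnonzero(s >= thr)
        if idx.size == 0:
            continue
        j = idx[0]
        if j > 0 and s[j] != s[j - 1]:
            j = j - 1 + (thr - s[j - 1]) / (s[j] - s[j - 1])
        lags[p] = j * kymo.line_interval_s
    pos = kymo.positions_um
    ok = np.isfinite(lags)
    if ok.sum() < MIN_FRONT_POINTS:
        raise RecordingError("no front: arrival detected on fewer than 3 rows")
    if np.ptp(lags[ok]) == 0:
        raise RecordingError("zero lag spread: no propagating signal")
    res = stats.linregress(lags[ok], pos[ok])
    front = pd.DataFrame({"time_s": lags[ok], "position_um": pos[ok]})
    return WaveFit(
        speed_um_s=float(abs(res.slope)),
        direction=1 if res.slope >= 0 else -1,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(ok.sum()),
        front=front,
        method="arrival-lag",
    )


# ---------------------------------------------------------------------------
# I/O


def load_kymograph(path: str | Path, pixel_um: float | None = None,
                   line_interval_s: float | None = None) -> Kymograph:
    """Read a kymograph from CSV (matrix) or single-page TIFF.

    Pixel size and line interval come from arguments or from a
    ``<stem>.meta.json`` sidecar with keys ``pixel_um``/``line_interval_s``.
    """
    import json

    path = Path(path)
    meta_path = path.parent / (path.stem + ".meta.json")
    meta: dict[str, Any] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    pixel_um = pixel_um if pixel_um is not None else meta.get("pixel_um")
    line_interval_s = (
        line_interval_s if line_interval_s is not None else meta.get("line_interval_s")
    )
    if pixel_um is None or line_interval_s is None:
        raise RecordingError(
            "kymograph needs pixel_um and line_interval_s (argument or sidecar)"
        )
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        values = tifffile.imread(str(path))
    else:
        values = np.loadtxt(path, delimiter=",")
    return Kymograph(
        values=values, pixel_um=float(pixel_um),
        line_interval_s=float(line_interval_s), meta=meta,
    )


def save_kymograph(kymo: Kymograph, path: str | Path) -> None:
    import json

    path = Path(path)
    np.savetxt(path, kymo.values, delimiter=",", fmt="%.17g")
    (path.parent / (path.stem + ".meta.json")).write_text(
        json.dumps(
            {"pixel_um": kymo.pixel_um, "line_interval_s": kymo.line_interval_s,
             **kymo.meta},
            indent=2,
        )
    )
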