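"""Recording, geometry and protocol I/O plus cell-adjacency derivation.

Time is stored in seconds, positions in micrometers, frames 0-based.
Event times are absolute recording time, never frame indices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

#: tolerance for declaring the time grid uniform (seconds)
TIME_GRID_TOL = 1e-6


class RecordingError(ValueError):
    """Raised when an input violates a recording invariant."""


@dataclass(frozen=True)
class PacingProtocol:
    """Electrical field-stimulation protocol.

    Parameters
    ----------
    stimulus_times
        Stimulus onset times in seconds, sorted ascending.
    rate_hz
        Nominal pacing rate (1-5 Hz typical).
    stop_time
        Time at which pacing was paused (pace-stop protocols); ``None``
        when pacing runs to the end of the recording.
    pulse_width
        Stimulus pulse width in seconds (metadata only).
    """

    stimulus_times: tuple[float, ...]
    rate_hz: float
    stop_time: float | None = None
    pulse_width: float = 0.005

    def __post_init__(self) -> None:
        st = tuple(float(t) for t in self.stimulus_times)
        object.__setattr__(self, "stimulus_times", st)
        if self.rate_hz <= 0:
            raise RecordingError(f"rate_hz must be positive, got {self.rate_hz}")
        if any(b <= a for a, b in zip(st, st[1:])):
            raise RecordingError("stimulus_times must be strictly increasing")
        if self.stop_time is not None and st and st[-1] >= self.stop_time:
            raise RecordingError(
                f"all stimulus_times must precede stop_time={self.stop_time}; "
                f"last stimulus at {st[-1]}"
            )

    def to_dict(self) -> dict[str, Any]:
        return {
            "stimulus_times": list(self.stimulus_times),
            "rate_hz": self.rate_hz,
            "stop_time": self.stop_time,
            "pulse_width": self.pulse_width,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PacingProtocol":
        return cls(
            stimulus_times=tuple(d["stimulus_times"]),
            rate_hz=float(d["rate_hz"]),
            stop_time=None if d.get("stop_time") is None else float(d["stop_time"]),
            pulse_width=float(d.get("pulse_width", 0.005)),
        )


@dataclass(frozen=True)
class CellGeometry:
    """Per-cell spatial metadata: centroids, optional grid coordinates,
    characteristic diameter.  ``table`` is indexed by cell id with columns
    ``x_um, y_um, row, col, diameter_um`` (row/col may be NaN for
    free-form ROIs)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"x_um", "y_um"}
        missing = required - set(self.table.columns)
        if missing:
            raise RecordingError(f"geometry table missing columns: {sorted(missing)}")
        if not np.isfinite(self.table[["x_um", "y_um"]].to_numpy(float)).all():
            raise RecordingError("geometry centroids must be finite")

    @property
    def cells(self) -> list[str]:
        return list(self.table.index)

    @property
    def has_grid(self) -> bool:
        return (
            "row" in self.table.columns
            and "col" in self.table.columns
            and self.table[["row", "col"]].notna().all().all()
        )

    def centroid(self, cell: str) -> tuple[float, float]:
        r = self.table.loc[cell]
        return float(r["x_um"]), float(r["y_um"])


@dataclass
class Recording:
    """A multicell fluorescence recording on a uniform time grid."""

    cells: list[str]
    times: np.ndarray
    fluor: np.ndarray  # [n_cells, n_frames], raw arbitrary units
    protocol: PacingProtocol
    geometry: CellGeometry | None = None
    meta: dict[str, Any] = field(default_factory=dict)
    allow_nan: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluor = np.asarray(self.fluor, dtype=float)
        if self.fluor.shape != (len(self.cells), len(self.times)):
            raise RecordingError(
                f"fluor shape {self.fluor.shape} does not match "
                f"({len(self.cells)} cells, {len(self.times)} frames)"
            )
        _check_uniform_grid(self.times)
        if not self.allow_nan and np.isnan(self.fluor).any():
            raise RecordingError("fluor contains NaN frames (strict mode)")
        t0, t1 = self.times[0], self.times[-1]
        for s in self.protocol.stimulus_times:
            if not (t0 <= s <= t1):
                raise RecordingError(
                    f"stimulus at {s} s lies outside recording [{t0}, {t1}] s"
                )
        if self.geometry is not None and list(self.geometry.cells) != list(self.cells):
            raise RecordingError("geometry cell ids must match recording cells exactly")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def trace(self, cell: str) -> np.ndarray:
        return self.fluor[self.cells.index(cell)]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected cell adjacency with a record of how it was derived."""

    cells: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    rule: str  # "grid-rook" | "centroid-distance:<d>"

    def __post_init__(self) -> None:
        known = set(self.cells)
        for a, b in self.edges:
            if a == b:
                raise RecordingError(f"self-edge on cell {a!r}")
            if a not in known or b not in known:
                raise RecordingError(f"edge ({a!r}, {b!r}) references unknown cell")

    def neighbors(self, cell: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == cell:
                out.append(b)
            elif b == cell:
                out.append(a)
        return sorted(out)

    def degree(self, cell: str) -> int:
        return len(self.neighbors(cell))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.cells)
        g.add_edges_from(self.edges)
        return g


def _check_uniform_grid(times: np.ndarray) -> None:
    if len(times) < 2:
        return
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        i = int(np.argmax(diffs <= 0))
        raise RecordingError(
            f"non-uniform grid: times not strictly increasing at interval "
            f"{i} ({times[i]} -> {times[i + 1]})"
        )
    dt = diffs[0]
    bad = np.abs(diffs - dt) > TIME_GRID_TOL
    if bad.any():
        i = int(np.argmax(bad))
        raise RecordingError(
            f"non-uniform grid: interval {i} is {diffs[i]:.9f} s, expected "
            f"{dt:.9f} s (tolerance {TIME_GRID_TOL} s)"
        )


# ---------------------------------------------------------------------------
# loading


def load_recording(
    path: str | Path,
    format_hint: str | None = None,
    protocol: PacingProtocol | None = None,
    geometry: CellGeometry | None = None,
) -> Recording:
    """Load a recording from a wide or long tabular trace file.

    Wide dialect: columns ``time, <cell>, <cell>, ...``; long dialect:
    columns ``cell, time, F``.  The dialect is taken from *format_hint*
    (``"wide"``/``"long"``) or sniffed from the header.  The pacing
    protocol comes from *protocol* or from a ``<stem>.protocol.json``
    sidecar; geometry from *geometry* or a ``<stem>.geometry.csv``
    sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    dialect = format_hint or _sniff_dialect(df)
    if dialect == "long":
        df = _long_to_wide(df)
    elif dialect != "wide":
        raise RecordingError(f"unknown format_hint {format_hint!r}")
    if "time" not in df.columns:
        raise RecordingError("wide trace table must have a 'time' column")
    times = df["time"].to_numpy(float)
    cells = [c for c in df.columns if c != "time"]
    fluor = df[cells].to_numpy(float).T

    if protocol is None:
        sidecar = path.with_suffix("").with_suffix(".protocol.json")
        alt = path.parent / (path.stem + ".protocol.json")
        for cand in (sidecar, alt):
            if cand.exists():
                protocol = PacingProtocol.from_dict(json.loads(cand.read_text()))
                break
    if protocol is None:
        raise RecordingError(
            f"no pacing protocol for {path.name}: pass protocol= or provide a "
            f"'{path.stem}.protocol.json' sidecar (or build one with "
            f"infer_protocol)"
        )
    if geometry is None:
        gpath = path.parent / (path.stem + ".geometry.csv")
        if gpath.exists():
            geometry = load_geometry(gpath)
    return Recording(cells=cells, times=times, fluor=fluor, protocol=protocol, geometry=geometry)


def _sniff_dialect(df: pd.DataFrame) -> str:
    cols = {c.lower() for c in df.columns}
    if {"cell", "time"} <= cols and ("f" in cols or "fluor" in cols):
        return "long"
    return "wide"


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    cols = {c.lower(): c for c in df.columns}
    fcol = cols.get("f") or cols.get("fluor")
    dup = df.duplicated(subset=[cols["cell"], cols["time"]])
    if dup.any():
        r = df[dup].iloc[0]
        raise RecordingError(
            f"duplicate (cell, time) rows: cell={r[cols['cell']]!r} "
            f"time={r[cols['time']]}"
        )
    wide = df.pivot(index=cols["time"], columns=cols["cell"], values=fcol)
    wide = wide.reset_index().rename(columns={cols["time"]: "time"})
    wide.columns.name = None
    # preserve first-appearance cell order from the long table
    order = list(dict.fromkeys(df[cols["cell"]].astype(str)))
    return wide[["time"] + order]


def infer_protocol(times: np.ndarray, fluor: np.ndarray, rate_hz: float | None = None) -> PacingProtocol:
    """Infer stimulus times from synchronized upstrokes of the mean trace.

    A fallback for trace files shipped without a protocol sidecar; peaks
    of the field-average derivative are taken as stimulus onsets.
    """
    from scipy.signal import find_peaks

    mean_f = np.nanmean(np.asarray(fluor, float), axis=0)
    d = np.diff(mean_f)
    if d.size == 0 or d.max() <= 0:
        raise RecordingError("cannot infer protocol: no upstrokes in mean trace")
    dt = float(times[1] - times[0])
    min_dist = max(1, int(0.1 / dt))
    peaks, _ = find_peaks(d, height=0.5 * d.max(), distance=min_dist)
    if peaks.size == 0:
        raise RecordingError("cannot infer protocol: no stimulus-like upstrokes")
    stim = times[peaks]
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(stim))) if stim.size > 1 else 1.0
    return PacingProtocol(stimulus_times=tuple(stim), rate_hz=rate_hz)


def load_geometry(path: str | Path) -> CellGeometry:
    df = pd.read_csv(path)
    if "cell" not in df.columns:
        raise RecordingError("geometry CSV must have a 'cell' column")
    df = df.set_index("cell")
    df.index = df.index.astype(str)
    return CellGeometry(table=df)


# ---------------------------------------------------------------------------
# trace extraction from image stacks


def extract_traces(
    stack: np.ndarray,
    roi_labels: np.ndarray,
    frame_interval: float,
    protocol: PacingProtocol | None = None,
) -> Recording:
    """Mean-ROI trace extraction from a T x H x W stack and an integer label map.

    Cells are ordered by ascending label; label 0 is background.
    """
    stack = np.asarray(stack, dtype=float)
    roi_labels = np.asarray(roi_labels)
    if stack.ndim != 3:
        raise RecordingError(f"stack must be T x H x W, got shape {stack.shape}")
    if roi_labels.shape != stack.shape[1:]:
        raise RecordingError(
            f"label map shape {roi_labels.shape} does not match frame shape "
            f"{stack.shape[1:]}"
        )
    labels = [int(v) for v in np.unique(roi_labels) if v != 0]
    if not labels:
        raise RecordingError("label map contains no ROIs (all background)")
    n_frames = stack.shape[0]
    fluor = np.empty((len(labels), n_frames))
    for i, lab in enumerate(labels):
        mask = roi_labels == lab
        if not mask.any():
            raise RecordingError(f"empty ROI for label {lab}")
        fluor[i] = stack[:, mask].mean(axis=1)
    times = np.arange(n_frames) * float(frame_interval)
    if protocol is None:
        protocol = PacingProtocol(stimulus_times=(), rate_hz=1.0)
    return Recording(
        cells=[f"roi_{lab}" for lab in labels],
        times=times,
        fluor=fluor,
        protocol=protocol,
    )


def read_tiff_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF / OME-TIFF as a T x H x W array."""
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr)


# ---------------------------------------------------------------------------
# adjacency


def adjacency_from_geometry(
    geometry: CellGeometry,
    rule: str = "centroid-distance",
    threshold_um: float | None = None,
) -> AdjacencyGraph:
    """Derive undirected cell adjacency.

    ``grid-rook`` links 4-neighbors of (row, col) grid coordinates;
    ``centroid-distance`` links pairs whose centroid distance is
    <= *threshold_um*.
    """
    cells = list(geometry.cells)
    edges: set[tuple[str, str]] = set()
    if rule == "grid-rook":
        if not geometry.has_grid:
            raise RecordingError("grid-rook adjacency requires row/col grid coordinates")
        pos = {
            (int(geometry.table.loc[c, "row"]), int(geometry.table.loc[c, "col"])): c
            for c in cells
        }
        for (r, c), cell in pos.items():
            for dr, dc in ((0, 1), (1, 0)):
                other = pos.get((r + dr, c + dc))
                if other is not None:
                    edges.add(tuple(sorted((cell, other))))
        tag = "grid-rook"
    elif rule == "centroid-distance":
        if threshold_um is None:
            raise RecordingError("centroid-distance adjacency requires threshold_um")
        xy = geometry.table[["x_um", "y_um"]].to_numpy(float)
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                if np.hypot(*(xy[i] - xy[j])) <= threshold_um:
                    edges.add(tuple(sorted((cells[i], cells[j]))))
        tag = f"centroid-distance:{threshold_um:g}"
    else:
        raise RecordingError(f"unknown adjacency rule {rule!r}")
    return AdjacencyGraph(cells=tuple(cells), edges=frozenset(edges), rule=tag)


def default_distance_threshold(geometry: CellGeometry) -> float:
    """1.5 x median cell diameter, the default for free-form ROI geometries."""
    if "diameter_um" not in geometry.table.columns:
        raise RecordingError("geometry lacks diameter_um; pass threshold_um explicitly")
    return 1.5 * float(geometry.table["diameter_um"].median())


# ---------------------------------------------------------------------------
# results writing

#: float format that round-trips IEEE doubles through text
_FLOAT_FMT = "%.17g"


def write_results(
    results: Mapping[str, Any],
    out_dir: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Write analysis tables as CSV plus a JSON manifest.

    *results* maps table name -> DataFrame or list of dataclass records.
    Returns the manifest (also written to ``manifest.json``).
    """
    from . import __version__

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise RecordingError(f"cannot write to {out_dir}: {exc}") from exc

    tables: dict[str, str] = {}
    for name, obj in results.items():
        df = _as_frame(obj)
        fname = f"{name}.csv"
        df.to_csv(out_dir / fname, index=False, float_format=_FLOAT_FMT)
        tables[name] = fname
    cfg = dict(config) if config else {}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": cfg_hash,
        "tables": tables,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def read_results(out_dir: str | Path) -> tuple[dict[str, pd.DataFrame], dict[str, Any]]:
    """Read back tables written by :func:`write_results`."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    tables = {
        name: pd.read_csv(out_dir / fname, float_precision="round_trip")
        for name, fname in manifest["tables"].items()
    }
    return tables, manifest


def _as_frame(obj: Any) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, (list, tuple)):
        if not obj:
            return pd.DataFrame()
        if dataclasses.is_dataclass(obj[0]):
            return pd.DataFrame([dataclasses.asdict(r) for r in obj])
        return pd.DataFrame(list(obj))
    if dataclasses.is_dataclass(obj):
        return pd.DataFrame([dataclasses.asdict(obj)])
    raise RecordingError(f"cannot serialize result of type {type(obj)!r}")


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as wide CSV with protocol (and geometry) sidecars."""
    path = Path(path)
    df = pd.DataFrame({"time": rec.times})
    for i, c in enumerate(rec.cells):
        df[c] = rec.fluor[i]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    (path.parent / (path.stem + ".protocol.json")).write_text(
        json.dumps(rec.protocol.to_dict(), indent=2)
    )
    if rec.geometry is not None:
        gt = rec.geometry.table.reset_index().rename(columns={"index": "cell"})
        if "cell" not in gt.columns:
            gt = gt.rename(columns={gt.columns[0]: "cell"})
        gt.to_csv(path.parent / (path.stem + ".geometry.csv"), index=False, float_format=_FLOAT_FMT)
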