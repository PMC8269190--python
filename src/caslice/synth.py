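"""Synthetic slice recordings and kymographs with known ground truth.

The generator emulates the statistical structure the analysis assumes:
paced transient trains with double-exponential kernels, beta-adrenergic
modulation of amplitude/decay/SCR rate, per-cell diastolic SCR Poisson
hazards with neighbor-coupling amplification, phenomenological ABAB
amplitude alternans, and traveling-wave line-scan kymographs.

Default calibration constants
-----------------------------
``SCR_RATE_CPVT_NE = 0.4`` events/s/cell for stimulated mutant slices.
``SCR_RATE_WT_NE = 0.1`` is back-calculated from the ~fourfold rate
difference between genotypes; no directly measured control value exists,
so treat it as a derived default.
``SCR_DURATION_MEAN_S = 0.9`` is the typical duration of a diastolic
release event; the coupling analysis uses it as its default window.

Coupling is implemented as hazard multiplication while any adjacent cell
has an ongoing event (a source-sink-source surrogate), not as Ca2+
diffusion between cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .io import (
    AdjacencyGraph,
    CellGeometry,
    PacingProtocol,
    Recording,
    RecordingError,
    adjacency_from_geometry,
)
from .kymo import Kymograph

import pandas as pd

SCR_RATE_CPVT_NE = 0.4  # events/s/cell, beta-AR stimulated mutant
SCR_RATE_WT_NE = 0.1  # derived: ~fourfold below the mutant rate
SCR_DURATION_MEAN_S = 0.9
#: the bump falls to ~8% of peak after this many decay taus; used to map a
#: requested event duration onto the kernel's decay constant
_DURATION_TO_TAU = 2.5


class SynthesisError(RecordingError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic slice recording.

    ``seed`` is mandatory; identical (config, seed) pairs give
    bit-identical output.
    """

    seed: int
    n_rows: int = 5
    n_cols: int = 8
    duration_s: float = 20.0
    frame_interval_s: float = 0.01
    pacing_rate_hz: float = 2.0
    pacing_start_s: float = 0.5
    stop_time_s: float | None = None
    # paced transient kernel
    amplitude: float = 1.0  # delta F/F0 at the peak
    rise_tau_s: float = 0.02
    decay_tau_s: float = 0.30
    # beta-adrenergic (NE) modulation
    ne_applied: bool = False
    ne_amplitude_mult: float = 1.5
    ne_decay_mult: float = 0.7
    ne_scr_rate_mult: float = 4.0
    # diastolic SCR model
    scr_rate_per_s: float = 0.0  # base per-cell hazard lambda
    scr_amplitude_frac: float = 0.3  # fraction of the paced amplitude
    scr_duration_mean_s: float = SCR_DURATION_MEAN_S
    scr_duration_sd_s: float = 0.07
    coupling_k: float = 1.0  # hazard multiplier while a neighbor's event is ongoing
    min_event_gap_s: float | None = None  # same-cell refractory gap; None = pure Poisson
    # alternans
    alternans_fraction: float = 0.0
    alternans_delta: float = 0.0  # small beats scaled by (1 - delta)
    alternans_tau_large_s: float | None = None
    alternans_tau_small_s: float | None = None
    # noise / scale
    noise_sd: float = 0.0  # raw fluorescence units
    f0_baseline: float = 100.0
    # geometry and labels
    cell_pitch_um: float = 20.0
    genotype: str = "WT"
    treatment: str = "basal"
    transient_lockout_s: float | None = None  # default 0.8 / pacing rate
    # fixture hooks: explicit per-cell beat-amplitude multipliers and the
    # matching ground-truth alternans flags
    amplitude_patterns: dict[int, tuple[float, ...]] | None = None
    pattern_truth: dict[int, bool] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SynthesisError("seed is mandatory")
        if self.scr_rate_per_s < 0 or self.pacing_rate_hz <= 0:
            raise SynthesisError("rates must be >= 0 and pacing rate positive")
        if self.coupling_k < 1:
            raise SynthesisError("coupling_k must be >= 1")
        if not 0 <= self.alternans_fraction <= 1:
            raise SynthesisError("alternans_fraction must lie in [0, 1]")
        if self.alternans_delta < 0:
            raise SynthesisError("alternans_delta must be >= 0")
        if self.decay_tau_s <= self.rise_tau_s:
            raise SynthesisError("decay tau must exceed rise tau")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def lockout_s(self) -> float:
        if self.transient_lockout_s is not None:
            return self.transient_lockout_s
        return 0.8 / self.pacing_rate_hz


@dataclass
class TrueScrEvent:
    cell: str
    onset: float
    amplitude: float
    duration: float
    coupled: bool  # onset fell inside a neighbor's ongoing event window


@dataclass
class GroundTruth:
    transient_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    transient_decay_taus: dict[str, np.ndarray] = field(default_factory=dict)
    scr_events: list[TrueScrEvent] = field(default_factory=list)
    alternans_positive: dict[str, bool] = field(default_factory=dict)
    speed_um_s: float | None = None
    diastolic_exposure_s: float = 0.0  # per-cell placement exposure


def biexp_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Double-exponential kernel normalized to unit peak; zero for t < 0."""
    if decay_tau <= rise_tau:
        raise SynthesisError("decay tau must exceed rise tau")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    tp = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)
    return np.clip(out, 0.0, None) / peak


def _stimulus_times(cfg: SimConfig) -> tuple[float, ...]:
    period = 1.0 / cfg.pacing_rate_hz
    end = cfg.duration_s if cfg.stop_time_s is None else min(cfg.stop_time_s, cfg.duration_s)
    stims = []
    t = cfg.pacing_start_s
    while t < end - 1e-12:
        stims.append(round(t, 9))
        t += period
    if not stims:
        raise SynthesisError(
            f"duration {cfg.duration_s} s too short to contain one stimulus at "
            f"{cfg.pacing_rate_hz} Hz starting {cfg.pacing_start_s} s"
        )
    return tuple(stims)


def _grid_geometry(cfg: SimConfig) -> tuple[list[str], CellGeometry]:
    cells, rows = [], []
    for r in range(cfg.n_rows):
        for c in range(cfg.n_cols):
            cid = f"c{r * cfg.n_cols + c:03d}"
            cells.append(cid)
            rows.append(
                {
                    "cell": cid,
                    "x_um": c * cfg.cell_pitch_um,
                    "y_um": r * cfg.cell_pitch_um,
                    "row": r,
                    "col": c,
                    "diameter_um": cfg.cell_pitch_um,
                }
            )
    table = pd.DataFrame(rows).set_index("cell")
    return cells, CellGeometry(table=table)


def simulate_slice_recording(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Simulate a paced multicell slice recording.

    Raw F per cell = F0_baseline * (1 + paced kernels + SCR bumps) +
    Gaussian noise.  SCR onsets are an inhomogeneous Poisson process
    restricted to diastolic frames, with hazard lambda * k while any
    adjacent cell's true event is ongoing.
    """
    if cfg.frame_interval_s > cfg.rise_tau_s:
        warnings.warn(
            "frame interval exceeds rise tau: transients are undersampled",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    stims = _stimulus_times(cfg)
    protocol = PacingProtocol(
        stimulus_times=stims, rate_hz=cfg.pacing_rate_hz, stop_time=cfg.stop_time_s
    )
    cells, geometry = _grid_geometry(cfg)
    n = len(cells)
    adjacency = adjacency_from_geometry(geometry, rule="grid-rook")
    nbr = np.zeros((n, n), dtype=bool)
    index = {c: i for i, c in enumerate(cells)}
    for a, b in adjacency.edges:
        nbr[index[a], index[b]] = nbr[index[b], index[a]] = True

    dt = cfg.frame_interval_s
    n_frames = int(round(cfg.duration_s / dt)) + 1
    times = np.arange(n_frames) * dt
    n_beats = len(stims)

    # --- per-cell beat amplitudes and decay taus -------------------------
    base_amp = cfg.amplitude * (cfg.ne_amplitude_mult if cfg.ne_applied else 1.0)
    base_tau = cfg.decay_tau_s * (cfg.ne_decay_mult if cfg.ne_applied else 1.0)
    n_alt = int(round(cfg.alternans_fraction * n))
    alt_cells = set(rng.choice(n, size=n_alt, replace=False).tolist()) if n_alt else set()
    alt_phase = {i: int(rng.integers(0, 2)) for i in sorted(alt_cells)}

    beat_amp = np.full((n, n_beats), base_amp)
    beat_tau = np.full((n, n_beats), base_tau)
    alternans_true: dict[str, bool] = {c: False for c in cells}
    for i in sorted(alt_cells):
        small = (np.arange(n_beats) + alt_phase[i]) % 2 == 1
        beat_amp[i, small] = base_amp * (1.0 - cfg.alternans_delta)
        if cfg.alternans_tau_large_s is not None:
            beat_tau[i, ~small] = cfg.alternans_tau_large_s
        if cfg.alternans_tau_small_s is not None:
            beat_tau[i, small] = cfg.alternans_tau_small_s
        alternans_true[cells[i]] = cfg.alternans_delta > 0
    if cfg.amplitude_patterns:
        for i, pattern in cfg.amplitude_patterns.items():
            p = np.asarray(pattern, dtype=float)
            # short patterns are tiled cyclically over the beat train
            reps = p[:n_beats] if p.size >= n_beats else np.resize(p, n_beats)
            beat_amp[i] = cfg.amplitude * reps
        if cfg.pattern_truth:
            for i, flag in cfg.pattern_truth.items():
                alternans_true[cells[i]] = bool(flag)

    # --- diastolic placement mask ---------------------------------------
    diastolic = np.ones(n_frames, dtype=bool)
    for s in stims:
        diastolic &= ~((times >= s) & (times <= s + cfg.lockout_s))
    exposure = float(diastolic.sum() * dt)

    # --- SCR event placement (frame-stepped thinning) --------------------
    lam = cfg.scr_rate_per_s * (cfg.ne_scr_rate_mult if cfg.ne_applied else 1.0)
    events: list[TrueScrEvent] = []
    event_end = np.full(n, -np.inf)  # end of each cell's latest event
    suppress_until = np.full(n, -np.inf)
    mean_cell_amp = beat_amp.mean(axis=1)
    if lam > 0:
        p_base = -np.expm1(-lam * dt)
        p_coupled = -np.expm1(-lam * cfg.coupling_k * dt)
        for fi in range(n_frames):
            u = rng.random(n)  # drawn every frame to keep the stream aligned
            if not diastolic[fi]:
                continue
            t = times[fi]
            ongoing = (event_end > t)
            has_src = nbr @ ongoing > 0
            p = np.where(has_src, p_coupled, p_base)
            fire = u < p
            if cfg.min_event_gap_s is not None:
                fire &= t >= suppress_until
            for ci in np.flatnonzero(fire):
                duration = float(
                    max(rng.normal(cfg.scr_duration_mean_s, cfg.scr_duration_sd_s), 4 * dt)
                )
                amp = cfg.scr_amplitude_frac * float(mean_cell_amp[ci])
                events.append(
                    TrueScrEvent(
                        cell=cells[ci],
                        onset=float(t),
                        amplitude=amp,
                        duration=duration,
                        coupled=bool(has_src[ci]),
                    )
                )
                event_end[ci] = max(event_end[ci], t + duration)
                if cfg.min_event_gap_s is not None:
                    suppress_until[ci] = event_end[ci] + cfg.min_event_gap_s

    # --- trace synthesis -------------------------------------------------
    signal = np.ones((n, n_frames))
    stim_arr = np.asarray(stims)
    for ci in range(n):
        for b, s in enumerate(stim_arr):
            i0 = int(np.searchsorted(times, s))
            i1 = min(n_frames, i0 + int(np.ceil((8 * beat_tau[ci, b]) / dt)) + 1)
            tt = times[i0:i1] - s
            signal[ci, i0:i1] += beat_amp[ci, b] * biexp_kernel(
                tt, cfg.rise_tau_s, beat_tau[ci, b]
            )
    for ev in events:
        ci = index[ev.cell]
        tau = max(ev.duration / _DURATION_TO_TAU, cfg.rise_tau_s * 1.5)
        i0 = int(np.searchsorted(times, ev.onset))
        i1 = min(n_frames, i0 + int(np.ceil((ev.duration + 8 * tau) / dt)) + 1)
        tt = times[i0:i1] - ev.onset
        signal[ci, i0:i1] += ev.amplitude * biexp_kernel(tt, cfg.rise_tau_s, tau)

    raw = cfg.f0_baseline * signal
    if cfg.noise_sd > 0:
        raw = raw + rng.normal(0.0, cfg.noise_sd, size=raw.shape)

    recording = Recording(
        cells=cells,
        times=times,
        fluor=raw,
        protocol=protocol,
        geometry=geometry,
        meta={
            "genotype": cfg.genotype,
            "treatment": cfg.treatment,
            "seed": cfg.seed,
            "coupling_k": cfg.coupling_k,
            "scr_rate_per_s": lam,
        },
    )
    truth = GroundTruth(
        transient_amplitudes={cells[i]: beat_amp[i].copy() for i in range(n)},
        transient_decay_taus={cells[i]: beat_tau[i].copy() for i in range(n)},
        scr_events=events,
        alternans_positive=alternans_true,
        diastolic_exposure_s=exposure,
    )
    return recording, truth


def simulate_kymograph(
    speed_um_s: float,
    cell_length_um: float = 100.0,
    pixel_um: float = 1.0,
    line_interval_s: float = 0.002,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 1.0,
    front_width_um: float = 2.0,
    pad_lines: int = 10,
) -> tuple[Kymograph, GroundTruth]:
    """Sigmoidal wavefront advancing at a constant speed, plus noise.

    The half-maximum of the noiseless front sits exactly at
    x = speed * (t - t0), so recovered front positions can be checked
    against the generator's own front equation.
    """
    if speed_um_s <= 0:
        raise SynthesisError("speed must be positive")
    n_pos = int(round(cell_length_um / pixel_um))
    if n_pos < 8:
        raise SynthesisError("cell must span at least 8 pixels")
    crossing_s = cell_length_um / speed_um_s
    if crossing_s < 3 * line_interval_s:
        raise SynthesisError("front exits the cell before 3 lines are recorded")
    t0 = pad_lines * line_interval_s
    n_lines = int(np.ceil((crossing_s + 2 * t0) / line_interval_s)) + 1
    x = np.arange(n_pos)[:, None] * pixel_um
    t = np.arange(n_lines)[None, :] * line_interval_s
    values = baseline + amplitude / (
        1.0 + np.exp(-(speed_um_s * (t - t0) - x) / front_width_um)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    kymo = Kymograph(
        values=values,
        pixel_um=pixel_um,
        line_interval_s=line_interval_s,
        meta={"true_speed_um_s": speed_um_s, "t0_s": t0, "front_width_um": front_width_um},
    )
    return kymo, GroundTruth(speed_um_s=speed_um_s)


# ---------------------------------------------------------------------------
# fixture registry


def _alternans_patterns(
    n_positive: int, n_constant: int, n_nine_beat: int, n_subthreshold: int
) -> tuple[dict[int, tuple[float, ...]], dict[int, bool]]:
    """Amplitude-multiplier patterns: true alternators at a 16.7% pair
    difference, traps at constant amplitude, 9-transient runs, and a
    just-below-threshold 9.5% difference."""
    patterns: dict[int, tuple[float, ...]] = {}
    truth: dict[int, bool] = {}
    idx = 0
    for j in range(n_positive):
        pair = (1.2, 1.0) if j % 2 == 0 else (1.0, 1.2)
        patterns[idx] = pair
        truth[idx] = True
        idx += 1
    for _ in range(n_constant):
        patterns[idx] = (1.0,)
        truth[idx] = False
        idx += 1
    for _ in range(n_nine_beat):
        nine = tuple(1.2 if b % 2 == 0 else 1.0 for b in range(9))
        # beats 9+ repeat beat 8's amplitude, so the run stops at 9 transients
        patterns[idx] = nine + (1.2,) * 55
        truth[idx] = False
        idx += 1
    for _ in range(n_subthreshold):
        patterns[idx] = (1.0, 0.905)  # 9.5% relative difference
        truth[idx] = False
        idx += 1
    return patterns, truth


def _alternans_fixture(seed: int, n_rows: int, n_cols: int,
                       counts: tuple[int, int, int, int]) -> tuple[Recording, GroundTruth]:
    patterns, truth = _alternans_patterns(*counts)
    cfg = SimConfig(
        seed=seed,
        n_rows=n_rows,
        n_cols=n_cols,
        duration_s=10.6,
        frame_interval_s=0.005,
        pacing_rate_hz=2.0,
        pacing_start_s=0.3,
        amplitude=1.0,
        rise_tau_s=0.02,
        decay_tau_s=0.10,
        noise_sd=0.0,
        amplitude_patterns=patterns,
        pattern_truth=truth,
        genotype="synthetic",
        treatment="NE",
    )
    return simulate_slice_recording(cfg)


def _scr_group(seed: int, rate: float, genotype: str) -> tuple[Recording, GroundTruth]:
    cfg = SimConfig(
        seed=seed,
        n_rows=5,
        n_cols=8,
        duration_s=120.0,
        frame_interval_s=0.01,
        pacing_rate_hz=2.0,
        pacing_start_s=0.3,
        stop_time_s=6.0,
        scr_rate_per_s=rate,
        scr_amplitude_frac=0.3,
        # short, sharp events keep same-cell overlap (and hence
        # detector-side merging) rare at 0.4 /s, so recovered rates stay
        # near lambda; placement is confined to the post-stop tail
        scr_duration_mean_s=0.05,
        scr_duration_sd_s=0.008,
        rise_tau_s=0.01,
        transient_lockout_s=1.6,
        coupling_k=1.0,
        noise_sd=1.0,
        genotype=genotype,
        treatment="NE",
    )
    return simulate_slice_recording(cfg)


def _coupling_fixture(seed: int, k: float) -> tuple[Recording, GroundTruth]:
    if k == 1.0:
        # independence check: moderate event footprint, plenty of sources
        cfg = SimConfig(
            seed=seed,
            n_rows=6,
            n_cols=7,
            duration_s=40.0,
            frame_interval_s=0.01,
            pacing_rate_hz=2.0,
            pacing_start_s=0.3,
            stop_time_s=6.0,
            scr_rate_per_s=SCR_RATE_CPVT_NE,
            scr_amplitude_frac=0.3,
            scr_duration_mean_s=0.3,
            scr_duration_sd_s=0.05,
            coupling_k=1.0,
            noise_sd=1.0,
            genotype="CPVT",
            treatment="NE",
        )
    else:
        # strong coupling: long events plus a same-cell refractory gap so the
        # hazard amplification produces repeated sweeping waves instead of a
        # saturated, undetectable cascade
        cfg = SimConfig(
            seed=seed,
            n_rows=12,
            n_cols=12,
            duration_s=45.0,
            frame_interval_s=0.01,
            pacing_rate_hz=2.0,
            pacing_start_s=0.3,
            stop_time_s=6.0,
            scr_rate_per_s=SCR_RATE_CPVT_NE,
            scr_amplitude_frac=0.3,
            scr_duration_mean_s=1.2,
            scr_duration_sd_s=0.05,
            coupling_k=k,
            min_event_gap_s=8.0,
            noise_sd=1.0,
            genotype="CPVT",
            treatment="NE",
        )
    return simulate_slice_recording(cfg)


def _pace_stop_fixture(seed: int) -> tuple[Recording, GroundTruth]:
    cfg = SimConfig(
        seed=seed,
        n_rows=5,
        n_cols=8,
        duration_s=23.0,
        frame_interval_s=0.01,
        pacing_rate_hz=2.0,
        pacing_start_s=0.3,
        stop_time_s=8.0,
        scr_rate_per_s=SCR_RATE_CPVT_NE,
        scr_amplitude_frac=0.3,
        scr_duration_mean_s=0.6,
        scr_duration_sd_s=0.07,
        coupling_k=1.0,
        noise_sd=1.0,
        genotype="CPVT",
        treatment="NE",
    )
    return simulate_slice_recording(cfg)


_FIXTURE_SEEDS = {
    "alternans_cpvt_25": 20251,
    "alternans_wt_24": 20252,
    "scr_ratio_groups": 20253,
    "coupling_null": 20254,
    "coupling_strong": 99,
    "pace_stop_basic": 20256,
}


def make_fixture(name: str, seed: int | None = None):
    """Materialize a named, seed-pinned synthetic dataset.

    Returns (Recording, GroundTruth) for single-recording fixtures and a
    dict of group label -> (Recording, GroundTruth) for
    ``scr_ratio_groups``.
    """
    if name not in _FIXTURE_SEEDS:
        raise SynthesisError(
            f"unknown fixture {name!r}; registry: {sorted(_FIXTURE_SEEDS)}"
        )
    if seed is None:
        seed = _FIXTURE_SEEDS[name]
    if name == "alternans_cpvt_25":
        # 11 true alternators, 14 traps (5 constant, 5 nine-beat, 4 at 9.5%)
        return _alternans_fixture(seed, 5, 5, (11, 5, 5, 4))
    if name == "alternans_wt_24":
        # 3 true alternators, 21 traps (7 constant, 7 nine-beat, 7 at 9.5%)
        return _alternans_fixture(seed, 4, 6, (3, 7, 7, 7))
    if name == "scr_ratio_groups":
        return {
            "high": _scr_group(seed, SCR_RATE_CPVT_NE, "CPVT"),
            "low": _scr_group(seed + 1, SCR_RATE_WT_NE, "WT"),
        }
    if name == "coupling_null":
        return _coupling_fixture(seed, k=1.0)
    if name == "coupling_strong":
        return _coupling_fixture(seed, k=20.0)
    if name == "pace_stop_basic":
        return _pace_stop_fixture(seed)
    raise AssertionError("unreachable")


FIXTURE_NAMES = tuple(sorted(_FIXTURE_SEEDS))
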