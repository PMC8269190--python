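"""Beat-to-beat Ca2+ alternans classification.

A cell is alternans-positive when consecutive transient amplitudes differ
by at least ``diff_frac`` (default 10%, inclusive) with strictly
alternating sign, sustained over at least ``min_run`` transients
(default 10; min_run transients = min_run - 1 qualifying pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RecordingError
from .transients import Transient

DEFAULT_DIFF_FRAC = 0.10
DEFAULT_MIN_RUN = 10


@dataclass
class AlternansCall:
    cell: str
    positive: bool
    run_length: int  # longest qualifying run, in transients
    mean_large_amplitude: float | None
    mean_small_amplitude: float | None
    mean_tau_large: float | None
    mean_tau_small: float | None
    phase: str | None  # "even" | "odd": stimulus-index parity of large beats
    flag: str = ""


def _pair_diff(a: float, b: float, denominator: str) -> float:
    if denominator == "max":
        den = max(a, b)
    elif denominator == "min":
        den = min(a, b)
    elif denominator == "mean":
        den = 0.5 * (a + b)
    else:
        raise RecordingError(f"unknown denominator rule {denominator!r}")
    if den <= 0:
        return 0.0
    return abs(a - b) / den


def classify_alternans(
    transients_of_cell: list[Transient],
    diff_frac: float = DEFAULT_DIFF_FRAC,
    min_run: int = DEFAULT_MIN_RUN,
    denominator: str = "max",
) -> AlternansCall:
    """Classify one cell from its stimulus-ordered transients.

    A qualifying run is a maximal stretch of consecutive transients in
    which every adjacent pair differs by >= *diff_frac* (relative to the
    larger amplitude by default) and the sign of the difference strictly
    alternates.
    """
    trs = sorted(transients_of_cell, key=lambda tr: tr.stim_index)
    cell = trs[0].cell if trs else ""
    n = len(trs)
    if n < min_run:
        return AlternansCall(
            cell=cell, positive=False, run_length=min(n, 1) if n else 0,
            mean_large_amplitude=None, mean_small_amplitude=None,
            mean_tau_large=None, mean_tau_small=None, phase=None,
            flag="insufficient beats",
        )
    amps = np.array([tr.amplitude for tr in trs])
    diffs = np.array(
        [_pair_diff(amps[i], amps[i + 1], denominator) for i in range(n - 1)]
    )
    signs = np.sign(np.diff(amps))
    qualifies = (diffs >= diff_frac) & (signs != 0)

    best_lo, best_hi = 0, 0  # run of transients [lo, hi] inclusive
    lo = 0
    i = 0
    while i < n - 1:
        if not qualifies[i]:
            i += 1
            lo = i
            continue
        j = i
        while j + 1 < n - 1 and qualifies[j + 1] and signs[j + 1] == -signs[j]:
            j += 1
        if (j + 1) - i + 1 > best_hi - best_lo + 1:
            best_lo, best_hi = i, j + 1
        i = j + 1
        lo = i
    run_len = best_hi - best_lo + 1 if qualifies.any() else 1
    positive = run_len >= min_run
    if not positive:
        return AlternansCall(
            cell=cell, positive=False, run_length=run_len,
            mean_large_amplitude=None, mean_small_amplitude=None,
            mean_tau_large=None, mean_tau_small=None, phase=None,
        )

    run = trs[best_lo:best_hi + 1]
    run_amps = amps[best_lo:best_hi + 1]
    # split the run into its two alternating phases
    phase0 = run[0::2]
    phase1 = run[1::2]
    if run_amps[0::2].mean() >= run_amps[1::2].mean():
        large, small = phase0, phase1
    else:
        large, small = phase1, phase0
    large_parity = "even" if large[0].stim_index % 2 == 0 else "odd"

    def _mean_amp(group):
        return float(np.mean([tr.amplitude for tr in group]))

    def _mean_tau(group):
        taus = [tr.decay_tau for tr in group if tr.decay_tau is not None]
        return float(np.mean(taus)) if taus else None

    return AlternansCall(
        cell=cell,
        positive=True,
        run_length=run_len,
        mean_large_amplitude=_mean_amp(large),
        mean_small_amplitude=_mean_amp(small),
        mean_tau_large=_mean_tau(large),
        mean_tau_small=_mean_tau(small),
        phase=large_parity,
    )


def alternans_fraction(calls: list[AlternansCall]) -> tuple[int, int, float]:
    """(n_positive, n_total, unrounded percentage)."""
    if not calls:
        raise RecordingError("alternans_fraction requires at least one call")
    n_pos = sum(1 for c in calls if c.positive)
    n_tot = len(calls)
    return n_pos, n_tot, 100.0 * n_pos / n_tot


def compare_decay_large_small(calls: list[AlternansCall]) -> pd.DataFrame:
    """Paired comparison of decay tau between large and small beats.

    One row per positive cell with valid tau on both phases, plus
    dataframe attrs carrying the paired-test summary (mean difference,
    95% CI, p).  A single usable cell yields the row but no p-value.
    """
    rows = []
    for c in calls:
        if c.positive and c.mean_tau_large is not None and c.mean_tau_small is not None:
            rows.append(
                {
                    "cell": c.cell,
                    "tau_large": c.mean_tau_large,
                    "tau_small": c.mean_tau_small,
                    "tau_diff": c.mean_tau_large - c.mean_tau_small,
                }
            )
    df = pd.DataFrame(rows, columns=["cell", "tau_large", "tau_small", "tau_diff"])
    if len(df) == 0:
        df.attrs["summary"] = {"n": 0, "flag": "no positive cells"}
        return df
    diffs = df["tau_diff"].to_numpy()
    summary: dict = {
        "n": len(diffs),
        "mean_diff": float(diffs.mean()),
        "direction": "large slower" if diffs.mean() > 0 else "small slower",
    }
    if len(diffs) >= 2 and np.std(diffs) > 0:
        res = stats.ttest_rel(df["tau_large"], df["tau_small"])
        sem = stats.sem(diffs)
        ci = stats.t.interval(0.95, len(diffs) - 1, loc=diffs.mean(), scale=sem)
        summary.update(p_value=float(res.pvalue), ci95=(float(ci[0]), float(ci[1])))
    else:
        summary["flag"] = "single cell or zero variance: no p-value"
    df.attrs["summary"] = summary
    return df


def calls_to_frame(calls: list[AlternansCall]) -> pd.DataFrame:
    cols = [
        "cell", "positive", "run_len", "A_large", "A_small",
        "tau_large", "tau_small", "phase", "flag",
    ]
    rows = [
        {
            "cell": c.cell,
            "positive": c.positive,
            "run_len": c.run_length,
            "A_large": c.mean_large_amplitude,
            "A_small": c.mean_small_amplitude,
            "tau_large": c.mean_tau_large,
            "tau_small": c.mean_tau_small,
            "phase": c.phase,
            "flag": c.flag,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=cols)
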