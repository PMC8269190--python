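# caslice

Calcium-imaging analysis for multicellular cardiac slice recordings:
F/F0 normalization, paced Ca²⁺-transient quantification, diastolic
spontaneous Ca²⁺-release (SCR) detection, beat-to-beat alternans
classification, pace-stop latency, intracellular wave-speed estimation
from line-scan kymographs, and intercellular SCR-synchronization
statistics against an independent-events Poisson null. A synthetic-data
generator emulates the slice experiment end to end, so every stage is
exercisable (and tested) without external data.

## Analysis rules (defaults)

- **F/F0**: F0 is the cell's minimum fluorescence (`f0_method="min"`).
- **SCR events**: contiguous diastolic regions above basal mean + 2 SD
  (robust, iteratively trimmed basal statistics), kept when their
  amplitude is ≥ 10% of the cell's mean triggered-transient amplitude;
  duration is the time between the bounding 2-SD crossings.
- **Alternans**: consecutive transient amplitudes differing by ≥ 10%
  (relative to the larger one, inclusive boundary) with strictly
  alternating sign, sustained for ≥ 10 transients.
- **Coupling**: for each source event, does any adjacent cell fire a new
  SCR within a window W (default: the source event's own duration)?
  The observed fraction `p_obs` is compared with
  `p_null = 1 − exp(−n_neighbors · λ · W)` for independent Poisson
  neighbors; a leave-one-out λ (secondaries excluded) is also reported.

Run `caslice show-config` to see every threshold with its provenance.

## CLI

```bash
caslice simulate pace_stop_basic --out fixtures/        # materialize a fixture
caslice analyze fixtures/pace_stop_basic.csv --out out/ # full pipeline
caslice alternans traces.csv                            # per-cell calls + fraction
caslice pacestop traces.csv                             # latency to first SCR
caslice kymo linescan.csv                               # wave speed (half-max or arrival-lag)
caslice coupling traces.csv                             # p_obs vs Poisson null
caslice report metrics.csv                              # group comparison (Welch/ANOVA)
```

Trace files are wide (`time,cell_1,...`) or long (`cell,time,F`) CSV/TSV
with a `<stem>.protocol.json` sidecar (stimulus times, rate, optional
`stop_time`) and an optional `<stem>.geometry.csv` (centroids, grid
coordinates, diameters). Image stacks (multi-page TIFF) plus an integer
ROI label map can be reduced to traces with
`caslice.io.extract_traces`.

## Fixture registry

`caslice.synth.make_fixture(name)` returns seed-pinned datasets with
ground truth:

| name | contents |
| --- | --- |
| `alternans_cpvt_25` | 25 cells at 2 Hz: 11 true alternators, 14 traps (constant, 9-transient runs, 9.5% differences) |
| `alternans_wt_24` | 24 cells: 3 true alternators, 21 traps |
| `scr_ratio_groups` | two 40-cell groups, λ = 0.4 vs 0.1 events/s/cell, 120 s |
| `coupling_null` | 42 cells, λ = 0.4 /s, coupling hazard multiplier k = 1 |
| `coupling_strong` | 144 cells, k = 20 with refractory gap (sweeping waves) |
| `pace_stop_basic` | 40 cells, 2 Hz pacing stopped at 8 s, λ = 0.4 /s tail |

## Layout

- `caslice.io` — recordings, protocols, geometry, adjacency, results I/O
- `caslice.synth` — synthetic recordings/kymographs + ground truth
- `caslice.transients` — F/F0, transient detection, decay fitting
- `caslice.scr` — SCR detection, rates, pace-stop latencies
- `caslice.alternans` — alternans calls, fractions, decay contrasts
- `caslice.kymo` — wavefront detection and speed estimation
- `caslice.coupling` — neighbor latencies, p_obs vs Poisson null
- `caslice.pipeline` / `caslice.cli` — orchestration, group stats, CLI
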