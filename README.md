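# rrow

Simulation and analysis of spike ensembles recorded along a linear probe
during a four-restaurant economic foraging task ("restaurant row").  The
package provides, as tested reusable components:

- **`rrow.synthetic`** — generators for task sessions (delay offers,
  threshold-governed accept/skip and quit/earn choices, linger periods) and
  for spike ensembles with planted tuning gains and directed pairwise
  coupling organized into blocks along a dorso-ventral axis.
- **`rrow.behavior`** — event-log parsing into skip/quit/earn visits,
  least-squares Heaviside threshold fits, subjective value
  (threshold − delay), reward ranking with earn-count tie-breaks, and
  cross-session threshold consistency.
- **`rrow.spikes`** — basic spiking properties (rate, CV, ISI stats, burst
  ratio), principal/interneuron classification, peri-event time histograms in
  absolute and zone-normalized time (20 in-zone + 3 pre + 3 post bins), and
  the circular-shift shuffle normalization used by every downstream analysis.
- **`rrow.information`** — plug-in mutual information between 5-bin
  discretized firing rates and task variables, as session summaries, per-bin
  time courses, and choice-conditioned splits.
- **`rrow.infoflow`** — pairwise transfer entropy (10 ms binarized bins,
  order-1 histories) with an input-only circular-shift null, 100 µm 2D
  anatomical mapping, 200 µm near-diagonal depth profiling, local-minima
  boundary detection, subregion assignment, and region-level TE statistics.
- **`rrow.dip`** — Hartigan's dip statistic (gcm/lcm algorithm) with a
  uniform-null Monte Carlo p-value, plus a weighted-profile adapter.
- **`rrow.popstats`** — firing/behavior correlations with shuffled-spike
  nulls, fixed-order and per-cell stepwise regressions, net choice-rate
  preferences with χ² proportion tests, subsampling controls, session-block
  analyses, and windowed rate correlations to offer delay and linger time.
- **`rrow.localization`** — cell depth reconstruction from peak waveform
  channel, probe geometry, and turn logs, with standardized-coordinate
  interpolation.
- **`rrow.io` / `rrow.cli`** — session bundles (plain CSV/JSON) and a seeded,
  deterministic end-to-end pipeline.

## CLI

```bash
# simulate a session bundle (events.csv, spikes.csv, cells.csv, config.json)
rrow simulate --config cfg.json --seed 1 --out bundle/

# individual stages
rrow behavior --bundle bundle/
rrow mi --bundle bundle/ --seed 1
rrow infoflow --bundle bundle/ --seed 1 --shuffles 30
rrow locate --bundle bundle/

# everything: visits, thresholds, spiking properties, MI, TE map,
# depth profile, subregion boundaries -> report/summary.json
rrow run-all --bundle bundle/ --seed 1 --out report/
```

`cfg.json` holds `"session"` and `"ensemble"` objects whose keys mirror
`SessionConfig` and `EnsembleConfig`.

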