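# looptrack

Closed-loop control of head-fixed 1D-track behavior experiments, fully
virtualized, plus the place-cell and decoding analyses used to validate
such rigs — with synthetic ground truth for every stage.

## Who this is for

Systems-neuroscience groups running head-fixed spatial navigation tasks
(treadmill belts or virtual-reality running wheels) need three things that
usually live in fragile rig-specific code: a reliable device messaging
layer, a task engine that turns encoder ticks into positions, laps,
rewards and stimulus switches, and an analysis pipeline that decides which
recorded ROIs are place cells and how well position can be decoded from
the population. looptrack implements all three as an installable,
seed-reproducible Python package in which every hardware component has a
software stand-in, so the full closed loop — simulated mouse → encoder →
engine → valve/display → log → analysis — runs in-process with exact
ground truth.

## What it computes

**Control plane.** Devices exchange single-datagram JSON messages
(`route`/`action`/`payload`/`id`/`t_ms`) with ack-based retry and
idempotent receivers. The engine integrates signed encoder ticks into
position on a circular track of length L (wrap increments the lap;
a physical lap-reset event cancels accumulated drift), evaluates
*contexts* — zone-gated stimulus groups modified by composable decorators
(even/odd laps, time windows, lap ranges, alternating blocks) — and
delivers operant or non-operant rewards at most once per lap per zone.
Every event streams to an append-only JSON-lines behavior log.

**Analysis.** For each ROI with deconvolved event amplitudes aligned to
position: binarize at median + 4·MAD of the raw trace; bin into 4 cm bins,
occupancy-normalize and smooth (Gaussian, SD = 2 bins) to a tuning curve
λᵢ; build a per-bin 99th-percentile threshold from 1000 per-lap circular
shuffles; call place fields on runs of 3–24 consecutive significant bins
(12 to < 100 cm) with events on ≥ 50% of laps. Per-cell metrics:
sensitivity, specificity, Skaggs spatial information
SI = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄) (bits/event), rate-map correlations and
population-vector shift alignment for remapping. Position is decoded with
a naive Bayes population decoder,

    P(pos | a) = C (∏ᵢ fᵢ(pos)^{aᵢ}) e^{−τ Σᵢ fᵢ(pos)},

cross-validated leave-one-lap-out with cell subsampling, against the
circular chance level L/4 or a cell-label-shuffle null. A pooled
two-proportion z-test compares place-cell fractions between conditions.

## Worked example

Simulate a session, generate a matched synthetic population, and analyze:

```
$ looptrack run --settings settings.json --duration 60 --seed 4 --out sess
behavior log: sess/behavior.jsonl

$ looptrack inspect sess/behavior.jsonl
records:  6070
laps:     4
rewards:  5
licks:    43
context 'rz': 5 intervals, 2400 ms active
```

Four complete laps in 60 s at the default ~150 mm/s on a 2 m belt; five
rewards because the reward zone was traversed on five laps (laps 0–4), one
reward per traversal; the reward context was active for the 2.4 s total
the mouse spent inside its zone.

```
$ looptrack synth --seed 5 --laps 20 --out bundle
session bundle: bundle (600 cells, 19 laps)

$ looptrack analyze --session bundle --seed 5
240/600 place cells; metrics: bundle/metrics.csv
```

The generator made 240 of 600 cells spatially tuned (fraction 0.4), and
the shuffle-test pipeline recovered exactly those — the metrics table
holds per-cell sensitivity, specificity and spatial information.

The same machinery is importable: `looptrack.BayesDecoder` is a
scikit-learn-style estimator (`fit(X, y)` on frames × cells activity and
per-frame position bins, `predict` / `predict_proba` on decoding windows),
and `looptrack.make_benchmark_suite(seed)` returns the standard fixture
families (tuned-rich, null, remapping pair, rotated pair).

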