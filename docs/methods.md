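# Methods

## Scope and model of the system

looptrack reproduces, entirely in software, the control plane of a
head-fixed 1D-track behavioral rig and the downstream place-cell analyses
that validate it. The system has two halves that share one message schema:

* **Control plane** — devices (position controller, behavior/GPIO box,
  display) exchange single-datagram JSON packets; a task engine integrates
  encoder ticks into calibrated position, evaluates context activation
  rules every step, actuates rewards and stimuli on edges, and streams a
  JSON-lines behavior log.
* **Analysis** — per-ROI deconvolved event-amplitude trains aligned to the
  position trace are binarized, turned into occupancy-normalized tuning
  curves, tested for spatial tuning by per-lap circular shuffling, and
  decoded with a naive Bayes population decoder.

Because no physical rig is present, every hardware element is replaced by a
virtual device with scripted transports, and a stochastic simulated mouse
supplies ground truth. Benchmarks that on a real rig would need an external
camera reference are re-expressed against the simulation's exact state.

## Wire format and reliability

One UTF-8 JSON object per datagram, at most 1400 bytes (single-MTU;
oversized messages are rejected at encode time, never fragmented). Top-level
keys: `route` (non-empty array of strings; the first element selects the
receiving handler, the rest pass down), `action`, `payload`, optional `id`
(per-sender monotone) and `t_ms` (ms since experiment start). Unknown
top-level keys are folded into the payload on decode so older receivers
tolerate newer senders. Reliability is stop-and-wait: acks are minimal
`{route:["ack"], payload:{id}}` messages; a sender retries the identical
`id` up to `max_retries` times (default 3, 100 ms timeout) and receivers
treat duplicate ids as idempotent. Unroutable messages become dead-letter
records rather than exceptions: a mis-addressed packet must never stop a
running session.

## Position tracking

Ticks arrive pre-decoded as signed deltas (quadrature decoding is the
counter hardware's job). Position is float mm in [0, L); forward motion
past L wraps by subtraction and increments the lap; backward motion floors
at 0 within a lap, so laps never decrease (wrapping backward past the seam
is a config-flagged alternative that is not enabled by default). On
circular tracks all distances are circular: d(a,b) = min(|a−b|, L−|a−b|).

The lap-reset sensor event zeroes the position and reports the signed
shorter-arc drift. A guard window of L/4 after a wrap suppresses
double-counting when both the software wrap and the physical reset observe
the same revolution: a reset seen at position < L/4 does not increment the
lap again. L/4 was chosen to be far larger than any plausible per-lap
drift and far smaller than a lap. Calibration estimates mm/tick as
belt length divided by the mean tick count over complete laps.

The virtual position controller transmits only on movement (one delta per
10 ms window, mirroring a 100 Hz counter poll), carrying the fractional
tick remainder forward so the stream conserves distance to within one
tick. When the belt crosses 0 mid-window the window's ticks are split
around the reset message, keeping the engine's integrated position within
one tick plus one window's travel of truth at every step. Belt slip is
modeled as proportional tick under-reporting (`slip_mm_per_lap`); without
resets this error grows linearly with lap count, with resets it is
re-zeroed each revolution — the drift recorded at each reset stays bounded
by the per-lap slip plus tick quantization.

## Task engine

Contexts are evaluated in settings-file order each step; position updates
are applied before context checks, and licks are latched per step. A
context's activation predicate is its base zone check (inside any of its
zones, or global when it has none) conjoined with its decorators
(`lap_parity`, `time_window`, `lap_range`, `alternation`). All decorators
are conjunctions, so stacking order cannot change the trace — a property
the tests verify by permutation. Unknown decorator kinds fail settings
validation at load, never at runtime.

Start/stop action messages are emitted only on activation edges, so
`count(start) − count(stop)` is always 0 or 1 per context; the termination
routine deactivates anything still on. Reward contexts trigger at most once
per lap per zone (the latch resets at lap increment): non-operant on zone
entry, operant only on a lick inside the zone. The session lifecycle is
setup (acknowledged sync pulse to the recording device; failure aborts),
main loop, termination (deactivation, stop pulse). With an injected clock,
a fixed epoch and a seeded rig, the log is byte-identical across runs.

Steps advance a logical clock at 10 ms per step by default. Simulated
sessions therefore run much faster than real time; a wall-clock mode is
not needed for any analysis in this package.

## Simulated mouse

Speed follows a discretized mean-reverting (Ornstein–Uhlenbeck) process,
clipped at 0, with Bernoulli-initiated pauses: mean 150 mm/s, SD 50 mm/s,
reversion rate 2 s⁻¹, pause probability 0.05 s⁻¹, pause length 1 s.
Licking is Bernoulli per 10 ms window at 0.5 Hz baseline, elevated inside
reward zones (default 8 Hz; tests that need guaranteed in-zone licking use
a rate high enough that the per-window probability saturates at 1). These
defaults are plausible for a trained head-fixed mouse but are conventions,
not measurements; every test that depends on them is a statement about the
software under these conditions, not about animal behavior. All randomness
derives from one seed through independent named substreams (motion, licks),
so components are independently reproducible.

## Synthetic place-cell populations

Generation starts at the deconvolved-event level (no fluorescence or
imaging-noise simulation). Cell i has a circular-Gaussian rate profile
rate(x) = b + (p − b)·exp(−d(x, c)²/2w²); untuned distractors have p = b.
Events are Bernoulli per 30 Hz frame with probability rate·Δt (specs
violating rate·Δt ≤ 1 are rejected), amplitudes lognormal(0, 0.5).
Defaults: 600 cells, 40% tuned (between commonly reported place-cell
fractions for virtual and physical 1D tracks), baseline 0.1 Hz, peak drawn
uniform 1–4 Hz, tuning SD 60–150 mm on a 2 m track. The benchmark suite
uses peaks of 2–5 Hz (≥ 20× the 0.1 Hz baseline) so that recovery failures
indicate algorithmic faults rather than SNR starvation, plus a fully
untuned family for null calibration, a centers-redrawn pair for remapping,
and a pair rotated by a known 7-bin shift for alignment recovery.

The generator shares the behavioral position trace, so generated occupancy
is identical to rig ground-truth occupancy by construction. What the
generator does **not** emulate: correlated noise across cells, slow drift,
multi-field cells, theta-phase structure, deconvolution artifacts, or
non-uniform occupancy beyond what the mouse model produces. Passing tests
therefore demonstrate correctness of the estimators under clean,
well-specified conditions, not robustness to every pathology of real
calcium imaging.

## Analysis pipeline choices

* **Binarization** — events kept above median(raw) + 4·MAD(raw). The MAD
  is deliberately unscaled (no 1.4826 normal-consistency factor); the
  factor is exposed as a parameter. A zero-MAD (constant) trace keeps all
  nonzero events with a warning.
* **Tuning curves** — 4 cm bins (B = round(L/4 cm)), rate = events/dwell
  per bin, Gaussian smoothing SD = 2 bins (8 cm) truncated at 4 SD,
  wrapping on circular tracks. Zero-dwell bins get rate 0 and are flagged.
  Pre-smoothing the curve conserves the event count exactly.
* **Shuffle test** — 1000 surrogates; each circularly shifts the events
  relative to position *within each lap* by an independent uniform frame
  offset, then recomputes the aggregate curve. Shifting events rather than
  occupancy is the identical operation (dwell is invariant under a relative
  shift) and is far cheaper because event frames are sparse. The per-bin
  threshold is the 99th percentile across surrogates. With 2-bin smoothing
  neighboring bins are correlated, so the *per-bin* exceedance rate is
  nominally 1% while exceedances cluster into runs; the binwise calibration
  check uses a 0.5–2% acceptance band to cover Monte-Carlo and tie/
  discreteness effects at realistic event counts.
* **Field criteria** — maximal supra-threshold runs (wrapping allowed),
  width 3–24 bins (12 to < 100 cm), and binarized events within the run on
  ≥ 50% of laps. No additional multiple-testing correction is layered on
  top; the run-length and reliability rules are the correction.
* **Sensitivity / specificity** — per field, then field-averaged per ROI.
  Specificity averages per-lap in-field fractions over laps with at least
  one event; zero-event laps are excluded rather than counted as 0, since
  an empty lap carries no evidence about event placement.
* **Spatial information** — Skaggs SI = Σ pᵢ(λᵢ/λ̄)log₂(λᵢ/λ̄) in
  bits/event; zero-rate bins contribute 0; λ̄ = 0 is flagged NaN.
* **Remapping** — Pearson correlation between per-cell rate maps; for
  belt-anchored recordings the single population-vector shift that
  maximizes the bin-averaged N-dimensional correlation is applied to the
  second context first (ties break to the smallest shift).
* **Decoder** — log P(pos|a) = Σᵢ aᵢ ln fᵢ(pos) − τ Σᵢ fᵢ(pos) + ln C,
  with fᵢ the mean binarized activity per bin converted to events/s and aᵢ
  the event count in a τ-second window. τ is interpreted as the decoding
  *time* window (default 0.5 s, configurable); the alternative reading of
  τ as the spatial bin size would make the exponential penalty
  dimensionally odd in a frame-based likelihood. Rates are floored at
  1e-4 events/s so the log-likelihood stays finite; decoding runs in log
  space; argmax ties break to the lowest bin index. Cross-validation is
  leave-one-lap-out; cell subsampling (default 500, all cells if fewer)
  selects decoder rows, so folds are fit once on the full population and
  reused across repeats (default 50). Chance is L/4 on a circular track
  (the closed-form expected circular distance between independent uniform
  points); elsewhere the cell-label-shuffle distribution is used, with
  p = (1 + #{shuffle ≤ observed})/(n + 1).
* **Trial = lap** throughout.

## Numerical and degenerate-input conventions

Positions exactly on a bin edge belong to the upper bin (floor indexing,
clamped to B−1). Pearson correlation of a zero-variance map, specificity
with no events, and SI with λ̄ = 0 return flagged NaN rather than raising.
The two-proportion z-test uses the pooled-variance form with a two-sided
normal p; a degenerate pooled proportion (0 or 1) returns NaN with a
warning. A truncated final log line is skipped with a warning; an
out-of-order record is monotonized and accompanied by an explicit error
record.

## Problem sizes in the validation suite

The test suite and the acceptance script size their simulations to be
statistically decisive while staying lightweight: null calibration uses
200 untuned cells × 30 laps × 1000 shuffles; field recovery uses 100 cells
(80 tuned) at benchmark SNR; decoding uses 100 cells, 30 laps, 10 subsample
repeats and 100 label shuffles; the closed-loop checks run a ~110 s
simulated session (~11 laps). These sizes give Monte-Carlo error well
inside every acceptance band; larger populations only shrink error bars.

## Known limitations

* The wire schema, settings schema and log layout are this package's own
  documented conventions for an otherwise unspecified rig protocol;
  interoperability with any physical rig firmware is not claimed.
* Decorators compose by conjunction only; disjunctive activation rules are
  out of scope.
* The simulated mouse has no spatial strategy (no anticipatory slowing,
  no licking onset before zones), so behavioral analyses beyond position/
  lick/reward bookkeeping are not meaningful on simulated sessions.
* The analysis assumes complete laps of a 1D track; open-field or
  fragmented-trajectory data are unsupported.
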