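# Methods

## Relative phase and its circular representation

Each tap is referred to its **nearest** metronome tick: `dt = tap − tick`,
`psi = −2π·dt/T` with `T = 60/bpm`. The negative sign makes psi positive
when tapping ahead, so a tapper running fast accumulates positive phase.
By construction `|dt| ≤ T/2` inside the tick grid. A tap exactly halfway
between two ticks is ambiguous; we resolve it to the *earlier* tick
(`dt = +T/2`, psi wrapping to π). The choice is deterministic and concerns
a measure-zero set; it is isolated in `nearest_tick_offset` so a
replication needing the opposite convention is a one-line change.

psi is wrapped to `[0, 2π)` and decomposed into `(cos psi, sin psi)`. All
internal phases are radians; degrees appear only at the region-boundary
API and in documentation.

**Unwrapping and laps.** The continuous trajectory is recovered by
minimal-step unwrapping: successive wrapped differences are mapped into
`(−π, π]` and accumulated. This assumes the true per-tap phase change is
below half a cycle — true whenever the tapper's detuning is below 100% and
motor noise is moderate (at 10 ms noise and `T ≥ 0.43 s` the noise term
contributes well under π/2). The lap count is
`floor(max forward excursion / 2π)`, where the excursion is measured from
the trajectory's first value and only positive drift counts (phasing is
defined by tapping *ahead*). A `1e-9` rad tolerance absorbs float error
when a trajectory ends exactly on a multiple of 2π. Labels follow directly:
1 lap = successful, ≥ 2 = unsuccessful, 0 = incomplete; a trial with no
taps raises an exclusion signal instead of a label.

## Recurrence analysis

The 2-D signal `(cos psi, sin psi)` is analysed unembedded (`EMB = 1`,
`DEL = 1`) — both coordinates of the system are already observed, so no
phase-space reconstruction is needed. No rescaling (`NORM = 'non'`) or
z-scoring is applied: both coordinates live on the same unit scale.
Recurrence uses an inclusive threshold `distance ≤ RAD` with `RAD = 1`;
on the unit circle the distance is the chord `2·sin(|Δpsi|/2)`, so the
criterion is exactly `|Δpsi| ≤ 2·arcsin(1/2) = 60°`. Inclusivity makes the
boundary case deterministic; pairs *exactly* on the 60° boundary are the
one place where floating-point rounding, not the mathematics, decides the
bit, and the test suite treats them accordingly.

Conventions for the metrics, chosen to match common MdRQA practice where
the source material is silent:

- **%REC** is the full-matrix density, line of identity (LOI) included in
  numerator and denominator.
- **%DET** and **MAXL** are computed from maximal diagonal runs at offsets
  `|k| ≥ theiler` with `theiler = 1` (LOI excluded), counting both
  symmetric halves; `lmin = 2`. The denominator of %DET is every off-LOI
  recurrent point. Note a fully recurrent N×N plot has
  `%DET = 100·(N²−N−2)/(N²−N) < 100`: the two corner diagonals are single
  cells, below `lmin`. %DET is *missing* (not 0) when no off-LOI recurrent
  point exists; all metrics are missing for series shorter than 2 points.
- The `norm` options rescale the phase-space points by their mean
  (`euclidean`), maximum (`maximum`) or smallest nonzero (`minimum`) point
  norm before distances are taken. They exist for generality, are
  exercised only for well-formedness, and are off by default.

**Region-based analysis** extracts the sub-series of taps whose wrapped
phase falls in r1 `[45°, 135°)`, r2 `[135°, 225°)` or r3 `[225°, 315°)`
(half-open boundaries exactly as stated; the synchronous complement is
excluded) and reruns the same analysis per region. Because restriction of
a pairwise-distance matrix to an index subset equals the distance matrix
of the extracted subsequence, region metrics coincide with metrics of the
corresponding full-plot submatrix — a tested identity. Regions with fewer
than `max(2, lmin)` taps report missing metrics.

## The simulator

The tapper is a first-order linear phase-correction process
(Vorberg–Wing style):

```
t[k+1] = t[k] + T/(1+δ[k]) − α[k]·A[k] + ε[k]
```

with `A[k]` the signed asynchrony to the nearest tick (same rule as the
analysis, keeping simulator and analyser aligned), `ε ~ N(0, σ²)`
truncated so tap order stays strictly increasing, and `α ∈ [0, 2)` (the
linear map is unstable at α ≥ 2 and construction rejects it). A trial is:
synchronized lead-in (δ = 0, α on; default 8 beats), a warning time, then
active phasing (δ > 0, α off — pure drift at `2π·δ/(1+δ)` rad per tap),
and, when `resync_stop` is set, resynchronization after the first
completed lap (δ = 0, α on, a few lead-out beats, stop).

Defaults mirror the study conditions: tempi 80–140 bpm in 10-bpm steps,
three repeats each, 21 trials per participant, 25 participants, trials at
most 120 s. Archetype presets generate the three trial types
(successful: detune 0.05 with resync; unsuccessful: same detune, never
resyncs; incomplete: never detunes, correction keeps it locked). The
detune default 0.05 (tapping 5% fast, one lap per ~21 taps) and correction
gain 0.3 are realistic values for deliberate phasing and human error
correction; cohort motor noise defaults to 10 ms, a typical tap-timing
jitter. The cohort draws each trial's archetype from the observed
38/41/21 trial-type mix. All randomness flows from a single seed;
identical seeds give byte-identical trial files.

**What the simulator is and is not.** It is a fixture generator exhibiting
the phenomena the analysis must handle — in-phase attraction, steady
drift, lapping, resynchronization — with closed-form ground truth (drift
rate, lap counts, region occupancy). It does not model antiphase
attraction, tempo-dependent rate limits, or group differences, so passing
tests demonstrate correctness of the *analysis chain*, not fidelity of any
behavioural theory; metric magnitudes on simulated cohorts are not
comparable to those of human data.

## Pipeline

`run_batch` classifies every trial, computes general metrics for all
analyzable trials and region metrics for successful/unsuccessful trials
only, and emits a long table keyed by participant, trial, tempo (raw and
binned lower/middle/upper), language group, trial type and scope. Zero-tap
trials are logged and excluded; any other per-trial failure is logged and
skipped without aborting the batch. Missing metrics serialize as empty
cells, and summaries report per-cell effective N (unweighted mean, sample
SD). Mixed-effects modelling is deliberately left downstream: the exported
table carries every fixed-effect column and the participant grouping key,
and deviation coding is a documented recipe for the modelling package of
choice, not something recomputed here.

## Problem sizes and determinism

The test suite and the acceptance script run on simulated data sized for
quick, repeatable execution: oracle comparisons use 200 random series of
length ≤ 40 (brute-force cost grows as N³), uniform-phase checks use 500
phases × 20 replicates, classifier recovery uses 300 noisy trials, and the
cohort checks use the full 25 × 21 design. Property tests are
derandomised/seeded; every stochastic test states its seed.

## Known limitations

- Lap counting is defined here via minimal-step unwrapping plus forward
  2π-excursion counting; the original experiment's operationalization is
  not documented, so agreement with its per-trial labels on archival data
  is an empirical question, not a guarantee.
- %REC/%DET/MAXL conventions (LOI in %REC, Theiler 1, `lmin` 2, symmetric
  counting) match widespread MdRQA defaults but other toolboxes differ;
  exact numeric replication of archival analyses requires matching that
  code's conventions. All conventions here are parameters or documented
  single-point changes.
- Analysis is event-based per tap, with no continuous-time interpolation
  between taps.
- Reading the archival MATLAB data format is out of scope; trials enter as
  the plain-text format documented in the README.
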