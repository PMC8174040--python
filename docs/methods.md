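# Methods

## The analysis model

Mean movement time (MT, first press onset to release of the last press) as
a function of viewing window size `w` is described by an exponential
saturation curve

    MT′(w) = a · exp(−b (w − 1)) + c ,

so that `MT′(1) = a + c` (pure serial production), `c` is the asymptotic
MT when further preview no longer helps, and `b` (1/item) is the rate at
which preview is converted into speed. The **effective planning horizon**
is the window size at which 99% of the benefit has been realized,

    w* = −ln(0.01)/b + 1 .

The 1% criterion is a convention: changing it multiplies `w* − 1` by
`ln(criterion)/ln(0.01)` and never reorders participants, so all
comparative statistics are criterion-invariant.

### Fitting

Fits use Levenberg–Marquardt nonlinear least squares on the 9 per-window
mean MTs of a participant (or participant × day), not on trial-level data:
the window means are the quantity the model describes, and equal weighting
keeps the noise model simple. `b` is optimized as `log b`, which enforces
`b > 0` (a negative decay has no interpretation here) while leaving the
optimizer unconstrained. Initialization follows the data
(`a₀ = MT(1) − MT(14)`, `c₀ = MT(14)`, `b₀ = 0.5`) with restarts over
`b₀ ∈ {0.2, 0.5, 1, 2}`; the best SSE wins. Flat input (zero MT range)
leaves `b` unidentifiable and the fit is flagged invalid and excluded
downstream, as are optimizer failures. Optimizer tolerances are set to
1e-13 so zero-residual inputs recover parameters to ~1e-6 relative.

## The generative model ("soft horizon")

The simulator exists so that every downstream stage has fixtures with
known ground truth. Its central design choice: the information-limited
component of every interpress interval (IPI) follows the *same*
exponential law as the analysis model,

    IPI(w) = c/13 + (sr − c/13) · exp(−b (w − 1)) ,

where `sr` is the single serial-response time (the w = 1 IPI, default
500 ms) and `c` the asymptotic MT component (default 2800 ms over 13
transitions). Summing 13 such transitions makes the scheduled MT exactly
`a·exp(−b(w−1)) + c` plus the final press duration, so parameter recovery
is well-posed: the generating `w*` of every participant × day is recorded
in the truth table and recoverable to machine precision in the noiseless
limit.

Two deliberate simplifications keep that exactness:

- The preview term uses `w − 1` for **all** transitions, without
  truncating at the end of the sequence. End-of-sequence dynamics are
  instead captured by an explicit speed-up (below); truncating the
  information count per transition would make the scheduled MT a mixture
  of exponentials and bias the recovered horizon by up to ≈0.4 items.
- The empirically robust speed-up of the **first and last** IPIs is a
  fixed subtractive discount (default 80 ms, floored at 40 ms) applied to
  transitions 1 and 13 for w ≥ 2 only. Because its total is constant in
  `w` (for w ≥ 2), it shifts the asymptote rather than the decay rate;
  residual bias in recovered `w*` is ≤ 0.13 items over horizons 2.5–4.5.
  For w = 1 no discount applies, so the w = 1 IPI profile is flat.

### Other generator components

- **Reaction time**: `RT = 450 + 75 · min(w, 4)` ms — initiation time
  grows with the amount preplanned and plateaus at the preplanning
  capacity (~3–4 items), giving ≈750 ms for large windows. RT is
  decision-limited and deliberately not scaled by the participant's
  execution-speed factor.
- **Practice**: compounding daily gains on the serial-response component
  (2.25%/day) and on the asymptotic/online component (11.8%/day), plus a
  linear horizon expansion of 0.17 items/day from a day-1 group horizon
  of 3.2 items. These reproduce ≈580 ms of w = 1 gain, ≈1100 ms of
  w = 14 gain, and a 3.2 → 3.9 item horizon over five days.
- **Heterogeneity**: per-participant lognormal multipliers on `w* − 1`
  (sd 0.25), on all scheduled times (sd 0.15), and on gaze lead (sd
  0.25). Log horizon and log speed are negatively correlated (−0.75):
  participants who plan further ahead execute faster at large windows.
  This coupling is what produces the strong negative across-participant
  correlation between horizon and large-window MT; heterogeneous decay
  rates alone cannot, because the large-`w` asymptote is `b`-independent.
- **Noise and errors**: multiplicative lognormal noise with CV 0.12 on
  RT, IPIs and press durations (strictly positive, right-skewed); each
  press is wrong independently with p = 0.0095, giving a trial error rate
  `1 − (1 − p)^14 ≈ 12.5%`, inside the study's 10–15% band.
- **Force traces**: each press renders as a half-sine pulse crossing 1 N
  exactly at the scheduled press time and falling below it at the release
  time, with strictly sub-threshold ramps; sampled at 200 Hz. Pulse shape
  is irrelevant by design — only the threshold crossings carry
  information, and detection recovers them within one sampling interval.
- **Eye**: gaze is a saccade-and-fixate step function that re-fixates
  midway between consecutive press onsets, leading the current press by
  `0.5 · min(w − 1, 4)` digits (times the participant gain), plus
  per-sample Gaussian noise (0.3 digits). For w = 1 the scripted lead is
  zero: nothing beyond the next item is visible.
- **Seeding**: every (participant, day, block, trial) derives its own
  stream from the master seed via hierarchical key-based seeding, so runs
  are bit-reproducible and extending the design (more participants, days
  or blocks) never perturbs already-generated trials.

## Trial processing conventions

- IPIs are differences of consecutive **press onsets** (upward 1 N
  crossings), consistent with the RT definition; releases enter only MT.
- A key must stay below threshold ≥ 20 ms before a new press on the same
  key registers (debounce); shorter dips are bridged.
- A trial is an error if any produced digit mismatches its target or the
  press count differs from 14; error trials are excluded from every
  RT/MT/IPI aggregate. Block medians for the adaptive threshold exclude
  error trials by default (a flag includes them); the threshold starts at
  the participant's first-block median when no explicit start is given.
- "5% or more faster" for the 3-point reward is inclusive:
  `MT ≤ 0.95 × threshold`.
- Positions are 1-based throughout (presses 1–14, transitions 1–13).

## IPI decomposition and aggregation

The preplanned/online boundary is fixed by the window size — transitions
1…min(w−1, 3) are preplannable, the rest are planned online, and all of
w = 1 is labeled `sr` (single-response) — rather than estimated per
participant. The final transition stays in "online" by default; a flag
excludes it as a robustness check since it carries its own end-of-sequence
speed-up. Aggregation is always participant-then-group so each participant
contributes equally regardless of trial counts. Normalized practice
improvement is `(early − late) / mean(early, late) × 100` within each
cell, which is invariant to a participant's overall speed.

## Statistics

Repeated-measures ANOVAs test each within-subject effect against its
subject × effect interaction (df `(a−1)`, `(a−1)(n−1)`); for two levels
this is exactly the squared paired t. The implementation delegates to
statsmodels' AnovaRM behind the package surface; zero-variance effects are
reported as F = 0, p = 1 rather than 0/0. No sphericity correction is
applied by default (Greenhouse–Geisser is out of scope) and no
multiple-testing correction anywhere — every test is reported as computed.
Subjects missing any cell are listwise-dropped with a logged warning.
Within-subject SEMs subtract each subject's mean across conditions (adding
back the grand mean) before computing per-condition SEMs; with a single
condition this is degenerate and yields 0 by construction.

The split-half horizon–MT analysis estimates `w*` from odd-numbered blocks
and mean MT for w > 5 from even-numbered blocks of the same day, removing
the noise-induced dependency between the two measures; participants with
fewer than two odd or two even blocks yield missing values.

## Problem sizes

The default generator reproduces the full study design (14 participants ×
5 days × 8 blocks × 27 trials). The test suite exercises most analyses on
a reduced cohort (10 participants, 4 blocks of 18 trials per day, all
rates and effect sizes unchanged) and runs the parameter-recovery check at
the full design for three generating horizons; the acceptance script runs
one full-design pipeline plus one full-design recovery.

## What the simulator does not capture

- No session-level random effects (day-to-day state, fatigue): the
  within-subject residual error is therefore unrealistically small, and
  tiny incidental day differences can reach significance in synthetic
  cohorts where the real study reported nulls (e.g. RT across days).
- No sequence-specific structure, chunking, or biomechanical transition
  costs — all transitions are exchangeable given `w`.
- No perceptual model of acuity/crowding; the eye script is a caricature
  (fixation steps tied to presses) adequate only for testing the
  gaze-mapping and profile machinery.
- Error presses are independent across positions; real errors cluster.

Passing tests therefore show that the pipeline recovers what this model
generates — not that the model is a complete account of real behavior.
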