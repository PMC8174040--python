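# seqhorizon

Simulation and analysis of **viewing-window discrete sequence production
(DSP) experiments** — the paradigm used to measure how far ahead the motor
system plans during rapid keypress sequences.

Participants produce 14-press sequences over the digits 1–5 on a
force-transducer keyboard while only the next `w` digits are visible
(`w ∈ {1,…,8,14}`, randomized within block, 8 blocks × 27 trials per day,
5 days). The package is aimed at motor-control researchers who want to
analyze such experiments — or prototype them against a fully specified
generative model before collecting data.

## What it computes

- **Trial processing** — keypress events from per-key force traces (1 N
  threshold crossings), reaction time (stimulus onset → first press),
  movement time (first press → last release), the 13 interpress intervals
  (IPIs), error flags, and the adaptive reward threshold / points rules.
- **Effective planning horizon** — per participant (× day), mean MT per
  window size is fit with Levenberg–Marquardt least squares to

  ```
  MT′(w) = a · e^(−b (w − 1)) + c
  ```

  and the horizon is the window size at which MT′ has dropped 99% of the
  way to the asymptote:

  ```
  w* = −ln(0.01) / b + 1
  ```

- **IPI decomposition** — each transition is labeled *preplanned*
  (transitions 1…min(w−1, 3)), *online* (the rest), or *sr* (all of w = 1),
  with placement profiles, middle-IPI (transitions 5–12) contrasts, and
  normalized practice-improvement scores per category.
- **Eye–press alignment** — gaze mapped to digit units,
  `D_t = 1 + (x_t − x0)/px` (median over a 25-ms window around each press),
  and press-relative lead profiles per day × window group.
- **Within-subject statistics** — repeated-measures ANOVAs (effects tested
  against their subject × effect interaction), paired/one-sample t tests,
  Pearson correlations, and within-subject SEMs from subject-centered
  residuals.
- **Synthetic experiments** — a "soft horizon" generative model whose
  scheduled MT follows the same exponential law, so the true `w*` of every
  simulated participant × day is known exactly (parameter-recovery ground
  truth).

## Worked example

```python
from seqhorizon import (GenerativeParams, PipelineConfig, run_pipeline)

cfg = PipelineConfig(params=GenerativeParams(seed=1))  # full 14×5×8×27 design
res = run_pipeline(cfg, outdir="results/run1")
print(res["horizon_by_day"][["day", "w_star_mean"]].round(2).to_string(index=False))
print(res["correlation"].round(3).to_string(index=False))
```

prints

```
 day  w_star_mean
   1         3.23
   2         3.42
   3         3.60
   4         3.77
   5         3.93
 day      r     p  n
   1 -0.442 0.114 14
   2 -0.450 0.107 14
   3 -0.407 0.148 14
   4 -0.419 0.136 14
   5 -0.428 0.127 14
```

i.e. the recovered group planning horizon expands from ≈3.2 to ≈3.9 items
over five practice days, and on every day participants with a larger
split-half horizon (fit on odd blocks) produce large-window sequences
faster (negative correlation with even-block MT for w > 5). Every tidy
table (MT/RT curves, fits, IPI profiles and category improvements, eye
profiles, ANOVAs, t tests, exclusion counts) is written to `results/run1/`.

The same operations are available from the shell:

```bash
seqhorizon simulate --seed 1 --out data/          # trial table + truth sidecar
seqhorizon process  --trials data/trials.csv --out proc/
seqhorizon analyze  --seed 1 --out results/       # full pipeline
seqhorizon recover  --horizons 2.5,3.5,4.5 --seed 1 --out recovery.csv
```

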