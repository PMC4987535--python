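# twostage

Simulation and analysis toolkit for a two-stage sequential decision task
with eye tracking: task generation, hybrid model-free/model-based
reinforcement-learning agents, per-subject maximum-likelihood fitting,
stay-probability and choice regressions, and a gaze-event pipeline — all
exercisable end-to-end on synthetic data with known ground truth.

## What's inside

| Module | Role |
| --- | --- |
| `twostage.task_engine` | Two-stage task sessions: per-trial Uniform(0.4, 1) common-transition probabilities (mean 0.7), reward probabilities drifting as reflected Gaussian walks (sd 0.025) in [0.25, 0.75], colour-deviation cues, 150-trial sessions for both conditions. |
| `twostage.agents` | SARSA(λ)-style model-free learner, Beta-Binomial transition learning with model-based valuation, hybrid weighting `w` (plus colour-cue weight `v` in condition 2), softmax choice with inverse temperature `β` and stickiness `p`. |
| `twostage.fitting` | Multistart Nelder-Mead ML fitting (numba-compiled likelihood), BIC model comparison, trial-by-trial Q-value derivation, median-split subject classification. |
| `twostage.behavior_stats` | Stay-probability tables, per-subject logistic stay regressions with group-level t-tests (mixed-effects surrogate), gaze-choice regression design and pooled cluster-robust fit. |
| `twostage.gaze_pipeline` | ROI assignment (400×290-px symbols + 50-px margin on a 1920×1080 screen), run-length event building, blink merging, trial exclusion, per-trial gaze statistics and bar-gaze share. |
| `twostage.synthetic_data` | Full synthetic studies: subjects drawn from documented priors, sessions from the hybrid agent, and gaze streams from two generative processes (value comparison vs directed search), optionally rasterised to 1000-Hz samples. |

## CLI

```bash
twostage simulate --out trials.csv --seed 1 --n-trials 150 --condition 1
twostage synth --n-subjects 43 --seed 7 --out study_dir/
twostage fit --trials trials.csv --model cond1_hybrid --starts 50 --out fits.json
twostage recover --n-subjects 40 --trials 300 --starts 50 --out recovery.csv
twostage stay-analysis --trials study_dir/trials.csv --condition 1 --out report.json
twostage gaze-stats --events study_dir/gaze_events.csv --out gaze_stats.csv
```

`twostage gaze-stats` also accepts raw samples (`--samples gaze_samples.csv`)
and a YAML geometry override (`--geometry geometry.yaml` with
`ScreenGeometry` fields).

## Notes

- Fitting bounds are enforced by smooth reparameterisation (logit for
  `α`, `λ`, `w`; stick-breaking for the condition-2 `(w, v)` simplex; log
  for `β`; soft clamp to ±10 for `p`); starts are drawn uniformly in the
  transformed space from a seeded generator, so every fit is reproducible.
- BIC uses `n_obs = 2·T` (both stage choices enter the likelihood).
- Group-level inference replaces mixed-effects estimation with per-subject
  ML plus across-subject tests (documented in each result's metadata).
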