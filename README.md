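# pathplan

Analysis toolkit for obstacle-avoidance path planning during walking:
walkway/obstacle geometry features, gaze allocation and sequencing, scanpath
alignment, logistic choice models, and a synthetic trial generator that
reproduces the statistical structure the analyses assume.

## What it does

- **`pathplan.layout`** — builds the eight walkway/obstacle conditions and
  derives the decision features per condition × target cell: relative
  distances to the obstacle's front corners (`d_left`, `d_right`,
  `delta_d`), deviation angles between the start→target ray and the
  start→corner rays (`theta_left`, `theta_right`, `delta_theta`), and the
  avoidance margins and their ratio (`am_left`, `am_right`, `amr`).
- **`pathplan.simulate`** — seeded synthetic trials over the full
  8 conditions × 3 target positions × n design: logistic path choices with
  a right-side bias at neutral geometry, piecewise trajectories that slow
  at narrow margins, phase-structured gaze streams over the AOIs, and 0–10
  judgment ratings from a logistic psychometric curve.
- **`pathplan.gaze`** — AOI construction (target / path / left / right
  margin), point labeling, dwell times, the avoidance-margin gaze ratio
  (AMGR, in [-1, +1]), dwell-weighted Gaussian allocation maps scaled to
  [0, 10], and gaze frequency tables.
- **`pathplan.scanpath`** — duration-normalized 100-symbol scanpaths
  (T/P/S with gap bins), Matrices A/B/C, Needleman–Wunsch similarity
  normalized to [0, 1] (identity or graded scoring), per-condition
  similarity tables, DTW-barycenter characteristic sequences, and FASTA
  export.
- **`pathplan.models`** — univariate and L1-selected multivariate logistic
  choice models (refit unpenalized on the selected set), label-shuffle
  surrogate p-values and case-resampling percentile CIs (batched IRLS
  engine), effect partition shares, leave-one-unit-out accuracy, AMGR
  models, and the judgment-test 50% threshold.
- **`pathplan.kinematics`** — anterior-posterior ankle gait speed (full
  path or up to the obstacle midline) and start-foot summaries.
- **`pathplan.pipeline` / CLI** — a reproducible simulate → features →
  sequence → model → report pipeline with manifests and provenance columns.

## CLI

```sh
# full pipeline into ./out with a fixed seed
pathplan run --stage all --seed 1 --out out

# individual stages (each reads its predecessors' artifacts from --out)
pathplan simulate --seed 1 --out out
pathplan features --out out
pathplan sequence --out out
pathplan model    --out out
pathplan report   --out out
```

Options come from an optional YAML config (`--config cfg.yaml`, keys
mirror `pathplan.pipeline.PipelineConfig`); CLI flags override config
values. Artifacts are plain CSV/JSON; `manifest.json` records the stage,
seed, config hash, and package version, and equal-seed runs are
byte-identical.

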