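# shoalstress

Group-level stress-response analysis for fish shoals.

Standard behavioural stress assays score animals one at a time, but most
laboratory fish are social and are housed — and increasingly tested — in
groups. `shoalstress` implements an analysis pipeline for the group-level
alternative: replicated shoals (e.g. 7 zebrafish per group) are observed in
a rectangular test tank in two conditions — `immediate` (right after
exposure to an acute stressor such as a novel tank) and `after_24h` — and
the pipeline quantifies how group structure, spatial preference, and
clip-level behaviours differ between conditions.

## What it computes

**Per-frame group metrics** from 2D top-down fish positions (cm, origin at
a tank corner), one frame every 10 s:

* *proximity*: mean and CV of nearest-neighbour distance
  (CV = s(NND)/mean(NND)), mean inter-individual distance, expanse (mean
  distance to the shoal centroid), convex-hull area;
* *spatial*: distance of the shoal centroid to the nearest wall
  (thigmotaxis);
* *social*: from a binary association matrix A, where A(i,j) = 1 iff fish
  i and j are within two mean body lengths of each other — network density
  (edges / n(n−1)/2) and subgroup structure (connected components).

**Clip-level behaviours** (10 s clips, presence = at least one fish shows
the behaviour during the clip): erratic movement and top-half occupancy,
plus intra-observer reliability statistics (percent agreement, Cohen's
kappa) and a rare-behaviour filter (presence < 10% pooled over both
conditions is dropped).

**Metric selection.** All candidate metrics are pairwise correlated
(Spearman for non-normal continuous pairs, Pearson otherwise) and greedily
pruned so that every retained pair has |r| < 0.2, while keeping at least
one metric per category (behavioural, social, proximity, spatial).

**Inference.** Each retained response y is tested for a condition effect
with a likelihood-ratio test between nested mixed models fitted by maximum
likelihood with a per-group random intercept u_g:

    continuous:  y = b0 + b1·condition + u_g + e        (Gaussian LMM)
    binary:      logit P(y=1) = b0 + b1·condition + u_g (binomial GLMM)

χ² = 2(ℓ_full − ℓ_null) on 1 df; the family of tests is
Bonferroni-corrected. Whole-body cortisol (ng/g) is analysed
log-transformed as its own a-priori test. The Gaussian models use
statsmodels `MixedLM`; the binomial marginal likelihood is maximised
directly via adaptive Gauss–Hermite quadrature (validated against lme4's
`glmer` in the test suite). `inference.paired_t_sample_size(4.0, 5.6,
power=0.9)` reproduces the design's sample size of 23 groups.

**Synthetic studies.** `shoalstress.simulate` generates complete studies —
trajectories from a zonal attraction/repulsion motion model with a single
stress parameter θ, behaviour tables derived from the sub-frame
trajectory, body lengths and cortisol — so the whole pipeline is testable
without any data collection. Under stress (θ = 1 vs 0.2) shoals are
denser, more regular, closer to the walls and the bottom, and more
erratic. See `docs/methods.md` for the model and its limitations.

## Worked example

```sh
shoalstress all --seed 3 --out-dir out
```

simulates a default study (23 groups × 7 fish × 2 conditions, 180 frames
and 180 clips per session), computes 8280 metric rows, selects metrics,
fits the mixed models and prints:

```
Condition differences (immediate vs after_24h), LRT on 1 df
----------------------------------------------------------------
response                           dir     chi_sq       p_adj
density                              +    10666.7      <1e-12
cv_nnd                               -     1523.5      <1e-12
distance_to_wall_cm                  -     7582.3      <1e-12
erratic_movement                     +     2017.1      <1e-12
cortisol_ng_per_g                    +        6.8     0.00931
----------------------------------------------------------------
```

Read: immediately after the stressor, shoals are significantly denser
(`+`), vary less in nearest-neighbour spacing, sit closer to the walls,
and show more erratic movement than the same groups 24 h later; whole-body
cortisol is higher too. Artefacts (`positions.csv`, `metric_table.csv`,
`correlation_matrix.csv`, `selection.json`, `results.csv`, `report.txt`,
`provenance.json`) land in `out/`.

The same stages are available as library calls
(`shoalstress.simulate_study`, `shoalstress.run_full_analysis`) and as
individual subcommands (`simulate`, `metrics`, `select`, `test`,
`report`).

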