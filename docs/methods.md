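# Methods

This note documents the models, conventions and design choices behind
`shoalstress`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and data model

The unit of replication is the *group* (shoal): each group of `n_fish`
(default 7) is observed in a rectangular tank (default 45 × 25 cm
footprint, 20 cm water depth) in two conditions, `immediate` and
`after_24h`, a repeated-measures design. A 30-minute session yields

* 180 *frames* of 2D fish positions (one every 10 s), the substrate for
  the proximity/spatial/social metrics, and
* 180 ten-second *clips*, each scored 0/1 per behaviour (presence = at
  least one fish shows the behaviour at any point in the clip).

Coordinates are continuous centimetres, origin at a tank corner, axes
along the walls, interval logic closed ([0, L]). Lens-distortion
correction, tracking and digitisation are assumed already done upstream.

## Group metrics

For a frame with positions x_1..x_n (2D):

* pairwise distances d(i,j) = ‖x_i − x_j‖;
* nearest-neighbour distance NND_i = min_{j≠i} d(i,j);
* CV NND = s(NND)/mean(NND), with the *sample* standard deviation
  (divisor n−1). The divisor is a convention choice, exposed as `ddof`;
  with 7 fish the difference to the population SD is ~8% and constant, so
  it cannot affect condition contrasts.
* mean inter-individual distance = mean over the n(n−1)/2 pairs;
* expanse = mean distance to the centroid (coordinate-wise mean);
* convex-hull area via Qhull, with collinear/degenerate frames defined as
  area 0;
* distance to nearest wall = min(cx, L−cx, cy, W−cy) for centroid (cx,cy).

Frames where all fish coincide (mean NND = 0) raise an explicit error
rather than yielding NaN: a NaN row would silently propagate into the
mixed-model fits downstream.

Association matrices use the threshold 2 × (group mean standard body
length), mm converted to cm (36.98 mm mean length → 7.396 cm). The
boundary is inclusive (d ≤ threshold counts as associating); with
continuous coordinates the boundary has measure zero, but the convention
is documented and configurable. Network density is the *pair* reading:
realised associations over n(n−1)/2 possible pairs, which is the only
reading bounded in [0,1]; the individual-count numerator (fraction of fish
with at least one association) is retained as
`associating_individual_fraction`. Subgroups are connected components of
the association graph (scipy's sparse `connected_components`; networkx is
used as an independent oracle in tests only).

## Behaviour coding and reliability

Behaviour tables are inputs (scored by a human from video, or derived by
the simulator); the package manages segmentation, filtering and
reliability. The rare-behaviour filter drops behaviours present in
strictly less than 10% of clips pooled over both conditions (exactly 10%
is retained — strict-less removal). Reliability on a re-scored clip subset
(default 10%, seed-reproducible selection) is summarised by percent
agreement and Cohen's kappa, κ = (p_o − p_e)/(1 − p_e) with p_e from the
marginal products. Degenerate cases: two identical constant coders have
perfect agreement (κ = 1 by convention); constant but different coders
return 0 with a warning, as chance correction is undefined there.

## Metric selection

Correlation method per pair: Pearson, except continuous–continuous pairs
where either member fails a Shapiro–Wilk normality screen (α = 0.05,
subsampled to ≤5000 values), which use Spearman. Pairs involving a binary
metric use Pearson (equivalently point-biserial/phi). Zero-variance
metrics get r = 0 with a warning. Missing values are handled
pairwise-complete, with the per-pair n recorded.

Selection is a greedy pass in a priority order: accept a metric iff its
|r| against every already-accepted metric is strictly below the threshold
(default 0.2; |r| exactly at the threshold counts as correlated).
Afterwards, any category (behavioural, social, proximity, spatial) left
unrepresented is repaired by admitting its member with the smallest
maximum |r| against the accepted set, logged as constraint-forced. The
default priority puts the canonical quintet (density, CV NND, wall
distance, erratic movement, top-half) first, remaining metrics
alphabetically; the criterion for choosing among correlated metrics is
user configuration, not inference. An exhaustive-search mode
(`select_metrics_exact`, ≤15 metrics) exists for verification; the greedy
result is always maximal (no excluded metric could be added) and matches
the exact optimum on block- and chain-structured correlation matrices.

Note that on synthetic data with strong condition effects, metrics from
different categories correlate *through the shared stress response* (e.g.
top-half vs density), so selection may legitimately retain fewer than five
metrics. The canonical five-response family can always be tested directly
via `AnalysisConfig(responses=[...])`, which bypasses selection and
Bonferroni-corrects exactly that family.

## Mixed-model inference

All models are fitted by maximum likelihood (not REML) so nested models
are comparable by likelihood-ratio tests: χ² = 2(ℓ_full − ℓ_null), 1 df,
clipped at 0 if numerically negative (independent optimisations can
produce tiny negative differences). The single random effect is a
per-group intercept, matching the repeated-measures design; observations
are per frame (continuous metrics) or per clip (behaviours). Condition is
coded immediate = 1, after_24h = 0, so a positive coefficient means
"higher under acute stress".

* Gaussian LMM: statsmodels `MixedLM` (ML). Non-convergence is flagged on
  the result rather than raised; a boundary (singular) random-effect
  variance is noted but the LRT is still valid.
* Binomial GLMM: the marginal likelihood of the random-intercept logistic
  model is a 1-D integral per group. With a binary covariate it depends on
  the data only through per-condition success/trial counts, and is
  evaluated by *adaptive* Gauss–Hermite quadrature (nodes centred at the
  per-group posterior mode with the Laplace standard deviation; 15 nodes
  by default, 1 node = Laplace approximation), maximised with L-BFGS-B
  (Nelder-Mead fallback). The test suite verifies agreement with R lme4's
  `glmer` (nAGQ = 15) to ~1e-3 on log-likelihoods and coefficients.
  All-zero/all-one responses and apparent complete separation (|b1| at
  bound) are flagged, not raised.

Families of tests are Bonferroni-corrected (p → min(1, m·p)); by default m
is the number of responses tested in the run. Cortisol is treated as its
own a-priori hypothesis (m = 1), configurable to join the family.
Cortisol is log-transformed; values recorded as 0 (below the ELISA
detection limit of 0.0567 ng/ml) are shifted by half the detection limit
with a warning before the log — the handling of such censored zeros is a
package convention, exposed as `cortisol_log_offset`.

`paired_t_sample_size` returns the smallest n of pairs for a two-sided
paired t-test to reach target power (statsmodels `TTestPower`, verified
against a Monte-Carlo oracle): detecting 4 ng/g at SD 5.6 ng/g with 90%
power needs 23 groups, which is the default study size.

## Synthetic-study generator

The generator exists so that every pipeline stage is testable end-to-end
with data whose ground truth is known. It emulates the study design
(23 groups × 7 fish × 2 conditions; 180 frames/clips per session; body
lengths N(36.98, 2.24²) mm; cortisol lognormal with condition means
40.2 / 19.9 ng/g and SDs 28.8 / 20.6 ng/g, i.e. SEs 6.0 / 4.3 at n = 23).

Motion is a deliberately minimal zonal scheme, per fish per 0.1 s
sub-frame: attraction to the centroid of the others
(w_att·(1 + κ·θ)), short-range linear repulsion (radius 2.5 cm),
constant-speed attraction towards the nearest wall, an
Ornstein–Uhlenbeck-like vertical coordinate relaxing to a preferred
depth, isotropic Gaussian locomotor noise, and rare large velocity
impulses ("erratic bursts", probability p0·(1 + β·θ) per fish per
sub-frame). Positions reflect at the walls. A single stress parameter
θ ∈ [0, 1] (1 = immediate, 0.2 = after 24 h) scales cohesion, wall
attraction, bottom preference and burst rate up, and locomotor noise
down. Behaviours are derived from the sub-frame trajectory: a clip is
erratic if any fish exceeds 60 cm/s (or turns >120° at >30 cm/s); it is
top-half if any fish rises above half the water depth. One frame per 10 s
is retained for the metric pipeline.

Two structural features matter for inference fidelity:

* *Group heterogeneity.* Each group carries a latent trait shifting its θ
  in both conditions (SD 0.06), and a share (ρ = 0.3) of the cortisol
  log-variance is a group effect shared across a group's two samples.
  Without these, groups are exchangeable and the random-intercept
  variance the models estimate would be identically zero.
* *Mixing time vs frame spacing.* The per-frame observational unit is only
  valid if the dynamics decorrelate within the 10 s frame interval. The
  slowest mode is the centroid's wall-distance coordinate at low θ; the
  default parameters include a condition-independent wall-attraction
  component (floor 0.15) and locomotor noise chosen so that this mode
  mixes fast enough in both conditions. This is verified behaviourally:
  with θ equal in both conditions, at most ~1 in 20 simulated studies
  shows any Bonferroni-adjusted p < 0.05 across the five-response family.

Seeding: one master seed spawns deterministic per-table and per-session
child seeds (`numpy.random.SeedSequence`); identical seeds give
bit-identical studies. Simulation kernels are numba-compiled.

What the generator does *not* emulate: real zebrafish kinematics
(burst-and-coast swimming, polarised schooling, visual interaction
networks), hydrodynamics, observer scoring noise, tracking error, or any
claim that the parameter values describe real fish. Passing tests
therefore show that the *pipeline* recovers known structure of the
assumed kind, not that the metrics behave identically on real video-coded
data.

## Problem sizes and numerical tolerances used in the test suite

* Metric oracle equivalence: 1000 seeded random frames (3–8 fish),
  relative tolerance 1e-9 against pure-Python brute-force oracles.
* Type-I calibration: 1000 null simulations per model family
  (Gaussian: 12 groups × 20 obs; binomial: 15 groups × 60 clips),
  rejection rate required within [0.03, 0.07] at α = 0.05.
* Parameter recovery: 50 master seeds of the full default study; all five
  directional effects significant after Bonferroni (m = 5) in ≥95% of
  seeds; an equal-θ null run flags any family member in ≤10% of seeds.
* GLMM cross-validation vs lme4: |Δ log-likelihood| ≤ 1e-3.
* Bulk and per-frame metric paths agree to ≤1e-12 relative.

## Known limitations

* The binomial GLMM supports exactly the design it is used for: binary
  condition covariate plus group random intercept (not arbitrary
  formulas).
* Metrics are 2D-only by design; the vertical coordinate is used only for
  deriving the top-half behaviour in the simulator.
* Greedy selection is order-dependent by construction; the priority list
  is explicit configuration, and the exact mode is exponential (≤15
  metrics).
* LRT p-values rely on the asymptotic χ²(1) null; with very few groups
  (< ~10) they become approximate, and the type-I calibration tests cover
  the study's size regime, not that limit.
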