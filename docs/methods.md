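# Methods

## Problem setting

The package implements a presence-background ensemble species-distribution
workflow for a montane habitat specialist. Two point sets drive two runs of
the same machinery: hair-sample presences define preferred habitat, and
carcass locations found after an extreme snowfall define mortality sites.
The scientific question is whether the two coincide — whether animals died
in their optimal habitat rather than in marginal areas — answered by
comparing selected variables, binary habitat maps and suitability surfaces
between the runs.

## Data model

All layers live on one aligned square grid (default 30 m cells) in
projected metres; cells are half-open so a point on a shared edge belongs
to exactly one cell (`row = floor((y0 − y)/cell)`, `col = floor((x −
x0)/cell)`). Rasters are stored as single-band ESRI ASCII grids, a plain
text format that round-trips values and nodata bit-exactly at full double
precision; layer kind (continuous / categorical / circular degrees) is
carried in the run configuration. Continuous layers resample bilinearly,
categorical and circular layers by nearest centre.

## Engineered covariates

* **Distance to feature** — exact Euclidean distance transform
  (centre-to-centre, metres); feature cells score 0.
* **Focal density** — area (m²) of a feature class within a circular window
  of radius 682 m, the male home-range radius (1.46 km²). Membership is by
  centre distance within the closed ball; edge windows are truncated, not
  renormalized, because the units are absolute m² per home range.
* **Terrain** — slope and aspect from the Horn 3×3 stencil with
  edge-replicated borders; flat cells have undefined aspect and are masked.
  Aspect is stored in degrees [0, 360) and enters discriminative models as
  a sin/cos pair; the envelope algorithms receive raw degrees, a documented
  caveat of the classic formulations.

## Preprocessing

* **Spatial thinning** enforces a minimum pairwise distance (default the
  682 m home-range radius) by a randomized greedy deletion — repeatedly
  remove one point, chosen uniformly among those with the most conflicting
  neighbours — repeated over 100 seeded restarts, keeping the restart that
  retains the most points. On a 12-point layout this matches the exhaustive
  maximum-independent-set answer.
* **Background points** are drawn uniformly without replacement over
  unmasked cell centres inside the study polygon. The mortality run always
  uses exactly 50; the habitat run defaults to 10× the presences in the
  full pipeline and to 300 (≈2× presences) in the benchmark scenarios,
  matching the mortality run's class balance so the two committees'
  calibrations are comparable.
* **Collinearity**: VIF_j = 1/(1 − R²_j) from regressing column j on the
  others plus intercept; the largest-VIF column is removed repeatedly while
  the maximum is ≥ 5. Perfectly collinear columns get an infinite sentinel
  that sorts above every finite value; ties break toward the earlier
  column.

## Variable selection

Candidates surviving the VIF screen are offered one at a time, in column
order, to the current set; passes repeat until a full pass adds nothing
(a variable rejected alone may be accepted once its partners are in). A
candidate is retained when three checks pass:

1. **Importance** — its average relative importance across all eight
   algorithms exceeds 5 %. Native importances (coefficient magnitudes,
   impurity) are used where the fitting routine provides them; BIOCLIM,
   Domain and Maxent use leave-one-variable-out CV (importance = 1 − AUC of
   the refit without the variable; the single-variable refit takes the
   no-predictor convention AUC 0.5 → importance 0.5). Before averaging,
   each algorithm's raw vector is made commensurable: the LOO importances
   first subtract the full-model null level (1 − AUC of the full model,
   which is exactly what a label-independent variable tends to), then every
   vector is rescaled by its maximum and normalized to sum to one.
   Dividing by the maximum, rather than min-max, keeps proportions: min-max
   sends the weakest variable to exactly zero, which with two variables
   erases the newcomer entirely.
2. **Predictive power** — the trial combination's best CV AUC among the
   envelope/Maxent members (computed anyway for the null level) must reach
   0.55, a weak any-real-skill floor. This is the selection loop's
   validation step; applying the final 0.80 bar to every partial
   combination would block the first variable unconditionally.
3. **Response shape** — the median response profile of the discriminative
   members (GLM, GAM, CART, RF, BRT; the envelope algorithms' profiles are
   tent-shaped around the presence median by construction and would corrupt
   the median) must be monotone or single-peaked. The profile varies one
   variable over its observed range with the others fixed at presence
   medians; classification fits a line and a parabola to the lightly
   smoothed profile: amplitude < 0.05 is flat ('other'), quadratic
   R² < 0.6 is uninterpretable ('other'), an interior valley is 'other'
   (the archetypal unexplainable relationship), otherwise the slope or the
   peak decides. Fit-based classification is robust to grid resolution and
   to tree-model jaggedness, where sign-pattern rules are not.

After the forward passes, backward prune steps drop the weakest retained
variable while any falls to ≤ 5 % relative importance.

## Evaluation, gate and ensemble

AUC is the Mann–Whitney statistic (ties half-counted). TSS is maximized
over midpoints of adjacent distinct scores plus sentinels; ties go to the
larger threshold, and prediction is positive at score ≥ threshold.
Cross-validation is stratified k-fold (default 10 folds × 50 repeats; each
repeat reshuffles with a seed derived from the CV seed), with mean ±
standard error over all fold scores. Algorithms with mean AUC ≥ 0.80 and
mean TSS ≥ 0.60 (closed bounds) enter the ensemble; an empty gate is a
flagged failure (CLI exit code 3).

The ensemble prediction is the cellwise median of member suitabilities
(mean of the central pair for even counts); masked cells stay masked. The
ensemble is evaluated by refitting every member inside each CV fold and
scoring the held-out median; the binarization threshold defaults to the
max-TSS threshold of the pooled held-out median scores.

## Mortality comparison

The carcass run clips the stack to the high-density polygon, draws its 50
backgrounds there and repeats the identical selection/gate/ensemble
machinery. `compare_runs` reports shared selected variables, the Jaccard
overlap of the two binary maps over the common unmasked cells (an empty
union counts as 1), and Spearman's rank correlation of the suitability
surfaces. The vulnerable-carcass statistic counts records whose age class
is Yearling or Juvenile (under three years; a strict Yearling-only reading
is available via a flag) or that were pregnant, over records with a known
age class, truncated — not rounded — to one decimal place: on the packaged
20-row table that is 17/19 → 89.4 %.

## Synthetic landscape generator

The generator is the package's test substrate and emulates the structure
the analysis assumes, not any particular real landscape. Smooth Gaussian
random fields (σ = 10 cells, so home-range-scale focal densities vary
across the default 200×200 grid) provide a DEM (700 ± 250 m) and latent
fields thresholded into feature classes (fields 5 % of cells, trails and
streams as thin bands, conifer/broadleaf cover around half); the covariate
module then derives the distance, focal-density and terrain layers exactly
as it would from real maps, and two pure-noise fields plus two noisy
copies of noise layers (altitude, distance to stream; relative noise 0.3)
complete the 12-layer stack.

True suitability is inverse-logit(β₀ + Σ β_v · standardized v) with
defaults β = +3.0 (distance to field), +2.4 (conifer focal density),
+1.8 (distance to trail) and β₀ = −6. The directions mirror the reported
habitat relationships; the magnitudes and the low intercept were fixed by
a design-time separability calculation: presences are drawn with cell
probability proportional to suitability, and a common species (β₀ near 0)
caps the achievable AUC near 0.75 no matter how strong the coefficients,
because presence draws from a mid-ranged suitability overlap the uniform
background heavily. A rare, strongly-determined specialist (β₀ = −6)
reproduces the strong-separation regime the method is meant for (oracle
AUC ≈ 0.92). Carcass samples can add a von-Mises-style weight centred on
135° (south-east aspect preference) with κ = 2; carcass count defaults
to 24.

What the generator does not emulate: survey effort bias, spatial
autocorrelation of residuals beyond the smooth fields, observation error
in the covariates, and temporal snow dynamics. Passing recovery tests
therefore show the machinery is correct and well-calibrated under the
stated generating model, not that real goral data would yield the same
selections.

## Benchmark problem sizes

The packaged benchmark scenarios run on one CPU: selection-time CV uses
4 folds × 1 repeat (the mortality run uses 4 × 5 — its 74-row table makes
repeats cheap and its max-TSS threshold needs them), habitat backgrounds
number 300, and the tree learners run lightened (RF 250 trees, BRT ≤ 300,
CART 3-fold pruning search) while the package defaults stay at the full
values (10 × 50 CV, RF 500). The parameter-recovery benchmark runs 20
seeds; the coincidence scenario runs 3 seeds and reports medians, because
the admitted member set occasionally produces a degenerately sharp habitat
committee on a single seed and the median is the appropriate single-number
summary of a scenario-level property.

## Numerical choices and limitations

* Stage seeds derive from one global seed via
  `SeedSequence([global_seed, stage_index])`; all stochastic learners are
  bit-reproducible for a fixed configuration, and two identical runs
  produce byte-identical artifacts.
* BIOCLIM's score reaches exactly 1 only where a presence sits at the
  componentwise median of every variable; Domain reaches 1 at every
  training presence.
* Ordinal soil-type variables are treated as continuous; circular aspect
  enters discriminative fits as sin/cos.
* The regression fits weight presences and backgrounds equally.
* Maxent here is the penalized-logistic formulation (lasso on linear +
  quadratic + hinge features with knots at training quantiles), not the
  Java application.
* The committee median is not calibrated across members: Domain's
  compressed similarity scale can sit far above the probability-scale
  members, and with small carcass samples the two runs' binary maps can
  differ substantially in area even when their suitability surfaces
  correlate strongly. In the coincidence scenario the binary-map Jaccard
  is therefore a noisy statistic at the study's sample sizes (24
  carcasses, 50 backgrounds): it lands on either side of 0.5 depending on
  the seed, while the rank correlation of the two suitability surfaces —
  reported alongside — expresses the same coincidence robustly.
* "Median of the model performance" is implemented as the cellwise median
  of member predictions; a literal median of performance metrics produces
  no map and cannot yield one.
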