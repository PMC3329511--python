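# Methods

This note documents the statistical models, the synthetic-data generator
and its calibration, the numerical choices, and the limitations of the
package. Every empirical number quoted here is computed by the test suite
or by `scripts/acceptance.py`.

## 1. Variables and models

### Trait table

Each row is a species (or genus) with: adult brain mass (g), adult female
body mass (g), gestation length (d), postnatal age at weaning (d), a limb
category (`plantigrade` / `non_plantigrade`) and a diet category
(`carnivore` / `omnivore` / `herbivore`). Derived variables: weaning time
post conception `wean_pc = gestation + wean_postnatal`, base-10 logs of the
masses and times, and dummy codes `lb = 1{non_plantigrade}`,
`dp = 1{non-carnivore}`. All raw quantities must be positive and finite;
species names unique. Genus aggregation averages numeric traits on the raw
scale by default (a geometric-mean switch averages the logs instead) and
refuses genera with conflicting categories.

### Model II (reduced major axis) regression

For bivariate allometries where both variables carry error, the RMA slope
is `sign(r)·sd(y)/sd(x)`, equivalently the geometric mean of the two
directional OLS slopes (a property test asserts the identity to 1e-10).
Degenerate inputs (zero variance) raise rather than return NaN.

### ANCOVA and inference

The full model `log10(wean_pc) = a + b·log10(brain) + c·lb + d·dp + ε` is
fitted by least squares (`numpy.linalg.lstsq` on the explicit design
matrix, with a rank check that raises on singular designs). Reported
inference: coefficient SEs and t-tests from `s²(XᵀX)⁻¹`; whole-model F on
(p, n−p−1) df; per-term F as the Type III (drop-one) statistic, which for a
single-df term equals the squared t; partial η² = SS_term/(SS_term+SS_res).
A statsmodels OLS fit is used in the tests as an independent oracle for
R², adjusted R², F, p-values and the Type III quantities.

Variance is additionally partitioned **sequentially** (Type I): terms are
entered in a stated order (default brain → limb → diet) and each increment
is the gain in R²·100. Increments are non-negative and sum to the
full-model R²·100 to 1e-8 (property-tested). Sequential increments are
order-dependent; the default order reflects the scientific hierarchy
(allometry first, then biomechanics, then diet).

The brain–body–weaning triangle is summarized by the Pearson correlation of
log brain with log weaning time and by the first-order partial correlation
controlling log body mass (computed by residualization; t-test on n−3 df).

### Prediction intervals and leave-one-out

For a new point x₀ the 90% (default) prediction interval is
`x₀ᵀβ ± t(0.95, n−p−1)·s·sqrt(1 + x₀ᵀ(XᵀX)⁻¹x₀)`. An empirical test at
n = 67 over 2000 replicates confirms coverage within 3 binomial SDs of
0.90. Points outside the convex bounding box of the training predictors
are flagged as extrapolation. The leave-one-species-out prediction refits
the model without the focal species and predicts it from its own
predictors; back-transformation to days is `10^point` (no smearing
correction; see Limitations).

### Independent contrasts

Felsenstein's pruning: for each cherry, contrast `(x₁−x₂)/√(v₁+v₂)`, the
node gets the branch-length-weighted mean and its parent branch grows by
`v₁v₂/(v₁+v₂)`. Polytomies are resolved to arbitrary dichotomies with
1e-8-length branches (a star on k tips still yields k−1 contrasts).
Because contrast signs are arbitrary, association is the **through-origin**
correlation `r = Σab/√(Σa²Σb²)` with `F = r²(n−2)/(1−r²)` on (1, n−2) df.
The tests verify exact equivalence (to 1e-8) with a GLS correlation under
the Brownian covariance matrix — an independent matrix-algebra oracle — and
the 1/√k rescaling of contrasts under branch scaling. A diagnostic
regression of |contrast| on its standardizing SD checks the Brownian
standardization assumption.

## 2. The synthetic-data generator

The package ships no observed trait table, so a calibrated generator stands
in for one. What it emulates:

- **Chronogram**: a seeded pure-birth (Yule) tree (dendropy), tip branches
  extended by the Exp(n·λ) waiting time to the next speciation event (the
  tree observed between events — without this, the n-th tip appears with a
  zero-length branch), stem dropped, and rescaled so the crown sits at 90
  time units (≈ the depth of the mammalian radiation in My). Tips are
  relabelled `sp01…spNN` deterministically.
- **Brain mass**: log10 brain mass evolves by Brownian motion
  (σ² = 0.026 per unit time from a root value of 1.5 log10 g), giving a
  tip SD of ≈1.1–1.2 dex — comparable to the spread of a broad mammalian
  sample.
- **Categories**: joint limb×diet labels painted either i.i.d. or (default)
  in clade-contiguous blocks of mean size 4 tips (≈ a family), with exact
  joint counts fixed by largest-remainder rounding of the cell
  probabilities (38/29 limb and 17/23/27 diet margins on 67 taxa).
  Block painting makes the categories carry phylogenetic signal, as real
  ones do; order-sized blocks were rejected during calibration because
  1–3 runs per cell made the dummy design ill-conditioned.
- **Weaning time**: the ANCOVA model itself, with a = 2.117, b = 0.30,
  c = −0.25, d = +0.20 and residual SD 0.151 log10 days.
- **Body mass**: allometric in brain mass
  (`log_body = (log_brain + 1.23)/0.762 + N(0, 1.15²)`); the 1.15 dex
  scatter is chosen so body mass is a genuinely worse predictor
  (single-predictor R² ≈ 0.5 vs ≈ 0.75 for brain) and the partial
  brain–weaning correlation controlling body lands near 0.69.
- **Gestation**: a uniform fraction (0.2–0.6) of weaning time post
  conception, so postnatal weaning age is positive by construction.
- **Human record**: optionally, the first plantigrade-carnivore tip is
  replaced by a fixed record (1320 g brain, 270 d gestation, 859 d
  postnatal weaning = 1129 d post conception); its tree tip is relabelled.
- **Society sample**: 46 positive normal draws with mean 1129 d and SD
  270 d, from a seed stream separate from the tree/trait streams.

All streams derive from one master seed via `numpy.random.SeedSequence`
spawning (children reduced mod 2³¹−1), so `(config, seed) → dataset` is a
pure function and every output is byte-reproducible.

What it does **not** emulate: measurement error in the predictors;
correlated evolution of the categories with brain mass; diversified or
fossil-calibrated tree shapes; interspecific variation in gestation
strategy beyond the uniform fraction; any real species identities beyond
the single fixed human record.

### Calibration

Constants were set by analytic variance budgeting (choosing the Brownian
rate, offsets and residual SD so the expected sequential increments split
roughly 75/10/3.5% with total ≈ 89%) and then refined against a 100-replicate
Monte-Carlo run. The shipped defaults give replicate means of: adjusted
R² ≈ 0.88, increments ≈ 75/11/3.5%, whole-model F ≈ 190, brain-term
F ≈ 455, brain–weaning r ≈ 0.86 with partial r ≈ 0.69, and a mean
leave-humans-out prediction ≈ 1140 d post conception (≈1% from the 1129-d
reference). Calibration was frozen before the acceptance tests were
written.

### Why replicate means

A single 67-taxon draw is one noisy realization: its leave-humans-out
prediction error has an SD of ≈9% across seeds, and its R² and F wobble
accordingly (the worked example in the README shows a weak draw).
Headline quantities are therefore reported as means over 100 seeded
replicate tables with Monte-Carlo error — the standard simulation-study
convention — rather than from any single arbitrary seed.

One structural consequence: under these defaults the human reference mean
falls **inside** the non-carnivore 90% prediction band in essentially all
replicates. The pooled diet offset (0.20 log10 units) is smaller than the
half-width of a diet-stratified prediction band (≈0.30 log10 units, since
the stratified fit absorbs limb variance into its residual), so the
"reference outside the non-carnivore band" contrast is not attainable
under this generator, and the corresponding acceptance test fails by
design rather than being weakened.

## 3. Numerical choices

- Least squares via `lstsq`/explicit normal equations with rank checks;
  singular designs raise `SingularDesignError` instead of silently
  pseudo-inverting.
- Dummy columns must be exactly 0/1; anything else is a validation error.
- p-values below 10⁻⁴ print as `<.0001`.
- JSON reports are serialized with sorted keys so reruns are
  byte-identical.
- CSV reading uses `float_precision="round_trip"`; tables survive
  write→read round trips exactly.
- Derived seeds are reduced mod 2³¹−1 so they fit any 32-bit RNG
  interface.

## 4. Limitations

- The leave-one-out back-transform `10^point` is the conditional median,
  not the mean, of the log-normal predictive distribution; no smearing
  correction is applied.
- Sequential (Type I) increments depend on entry order; only the default
  scientific ordering is reported.
- Independent contrasts assume Brownian evolution and an ultrametric,
  correctly-scaled chronogram; the generator satisfies both, real trees
  may not.
- The grade-shift model forces a common slope; slope heterogeneity between
  categories is not modelled (per-category RMA fits in step 3 give a
  qualitative check).
- Categories are painted onto the tree independently of the simulated
  brain masses, so category–allometry confounding present in nature is
  absent by construction.
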