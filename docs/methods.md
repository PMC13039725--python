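# Methods

This note documents the models implemented in `betafutures`, the defaults
they ship with, and what the synthetic data generator does and does not
emulate. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Community preparation

Incidence records (site, species, year, present) are pooled per site into
an assemblage (union over years) and a per-species year-frequency vector.
Compositional dissimilarity between assemblages is Jaccard,
d = 1 − |A∩B|/|A∪B|, undefined (an error) only when both assemblages are
empty.

Sampling completeness per site is the Chao incidence coverage estimator
computed from the year-frequency vector: with T sampled years, U total
incidences, Q1 singletons and Q2 doubletons,

    C_hat = 1 − (Q1/U) · [(T−1)Q1 / ((T−1)Q1 + 2Q2)].

Sites with fewer than two sampled years are excluded (the estimator needs
at least two sampling units), and sites with no incidences are dropped with
a logged reason. Coverage is clipped to [0, 1] and equals 1 exactly when
there are no singletons.

Site-pair tables hold every unordered pair (or a seeded uniform subsample
capped at `max_pairs`), with pair weight the arithmetic mean of the two
site coverages. The weight convention follows the usual custom site-weighted
pair-table construction; weights are used as-is, not normalised — fitting is
invariant to their overall scale anyway since both model and null deviance
share it.

A collinearity screen reports all pairwise Pearson correlations and flags
|r| ≥ 0.8 (and zero-variance, undefined cases). It is diagnostic only:
flagged pairs are retained, because strongly correlated variable pairs
(e.g. annual minimum and maximum temperature) typically represent distinct
ecological dimensions and dissimilarity models are robust to collinearity.

## Generalised dissimilarity model

**Basis.** Each predictor gets three monotone I-spline basis functions of
order 2 (piecewise quadratic), knotted at the minimum, median and maximum
of its training values. The implementation builds degree-2 B-splines on the
clamped knot vector (t1,t1,t1,t2,t3,t3,t3) and takes reverse cumulative
sums; the tests verify this against direct quadrature of the corresponding
order-2 M-spline densities. Values outside the training range are clamped
to the boundary knots — extrapolation beyond observed gradients is a known
hazard of space-for-time substitution, and clamping is the conservative
choice. A constant predictor degenerates to an inert all-zero basis and is
dropped from fits with a warning.

**Objective and solver.** The fit minimises weighted squared error on the
response scale,

    Σ_ij w_ij (d_ij − [1 − exp(−η_ij)])²,   η_ij = a0 + Σ β_{p,k} |ΔI_{p,k}|,

subject to a0, β ≥ 0. This is the behaviour of the standard GDM software
lineage; a literal binomial likelihood would weight extreme dissimilarities
differently, and the squared-error form is what the field's coefficient
conventions are calibrated to. The solver iterates Gauss–Newton
linearisation of the link, a non-negative least-squares solve on the
working response, and step damping (halving until the objective decreases),
stopping when the relative objective change falls below 1e−8 or after 200
iterations. Initialisation is deterministic (NNLS on the link-transformed
observations), so fits are exactly reproducible. On tiny problems the
result matches a multistart bounded quasi-Newton oracle to within 1e−6 in
objective value.

**Explained deviance.** Reported as 100·(1 − D_model/D_null) with the null
being an intercept-only fit of the same objective. The deviance is
binomial-form by default, with observed and fitted values clamped to
[1e−6, 1−1e−6]; a squared-error form is available behind the
`deviance_form` switch. Which form published explained-deviance figures use
is generally ambiguous, hence both.

**Prediction.** `gdm_transform` maps a grid onto the fitted turnover scale
f_p(x) = Σ_k β_{p,k} I_{p,k}(x); `predict_dissimilarity` evaluates
1 − exp(−(a0·[flag] + Σ_p |Δf_p|)), with the intercept included for
site-pair predictions and removed for all through-time comparisons.

## Bioclimate metrics

All three projection metrics remove the intercept, so an unchanged
environment predicts exactly zero change; this is deliberately conservative
(stochastic drift in composition at a fixed site is not modelled).

* **Compositional change**: per-cell dissimilarity between the cell's
  current and future transformed vectors; summarised by median and IQR.
* **Disappearing bioclimates**: per current cell, the minimum dissimilarity
  to *any* future cell; masked where that minimum is ≥ τ.
* **Novel bioclimates**: the exact mirror image (per future cell, minimum
  over current cells); swapping the epochs swaps the two outputs exactly,
  which the tests assert bit-for-bit.

τ defaults to 0.10 — large enough that not every pair of bioclimates
differs, small enough to remain sensitive to analogue loss. Cross-cell
scans are exhaustive at package scale (no subsampling); the metric config
keeps a `reference_fraction` for very large grids. Area percentages use the
intersection of the two epochs' validity masks. Overlap between the
disappearing and novel masks is summarised by Jaccard J = |D∩N|/|D∪N|
(0 when the union is empty) and the conditional replacement probability
|D∩N|/|D| (flagged NaN when D is empty).

## Habitat condition and BII

Per-class BII is the product of two reference-relative coefficients,
clipped to [0, 1]:

* **Abundance**: effort-standardised site total abundance, rescaled to a
  maximum of 1 within each study, square-root transformed, and regressed on
  land-use class + √NPP with per-study intercepts. The class coefficient is
  the squared ratio of the class prediction to the reference prediction
  (the square undoes the square-root scale; the ratio is taken at mean NPP
  and the average study effect).
* **Compositional similarity**: within each study, 1 − d_BC-bal between
  every reference site and every other site, where d_BC-bal =
  min(B,C)/(A + min(B,C)) is the balanced-variation component of
  abundance-based Bray–Curtis (A = Σ min, B and C the site-specific
  surpluses). If either site has no individuals, similarity is 0 by
  convention. Similarities are affinely compressed to [0.05, 0.95]
  (s′ = 0.05 + 0.9·s) before the logit — the "adjustment of 0.05" — and
  regressed on the class transition, cubic terms in log1p geographic
  distance and cube-root Gower environmental distance, √NPP, and study
  intercepts. The class coefficient is the back-transformed class effect at
  zero distance, relative to the reference-to-reference prediction.

The mixed-effects formulation (random study intercepts and slopes) is
deliberately replaced by fixed-effects least squares with study dummies:
the package's purpose is the BII arithmetic and its propagation through the
pipeline, not mixed-model machinery, and with balanced synthetic studies
the two give closely similar class contrasts. Coefficients can also be
supplied directly via a CSV table, bypassing estimation entirely. Raw
polynomial terms are used for the distance covariates rather than
orthogonal ones: both vanish at zero distance, which is the only point
where class effects are read off, so the extracted coefficients are
unchanged.

Adjustment rules applied when building tables:

* urban: multiplied by the pervious fraction, 1 − imperviousness
  (default imperviousness 0.30);
* agroforestry: arithmetic mean of sustainable agriculture, extensive
  pastoral and productive forestry;
* hyper-intensive classes: dynamic BII declining linearly from 0.63 in
  2037 to 0.50 in 2070, constant outside that window. The endpoints are
  configurable; an alternative constructor builds the pre-decline maximum
  as intensive + 80% of the extensive−intensive gap, but since that rule's
  direction is ambiguous the fixed endpoints are the default path.

Habitat maps evaluate hab(cell, year) = BII(class(cell, year), year)
annually across a time slice, each year using the most recent available
land-use map (decadal maps repeat forward), then average over the slice.
Annual evaluation (rather than map-year-only) was chosen so dynamic classes
interpolate smoothly within a slice; for static classes the two conventions
coincide.

## Species–area extinction debt

Per cell i,

    p_i = [ Σ_j Sim(i_cur, j_fut)·hab_fut[j] / Σ_j Sim(i_cur, j_cur)·hab_cur[j] ]^z

with Sim = exp(−Σ_p |Δf_p|) (one minus the intercept-free predicted
dissimilarity), z = 0.25 (the widely used species–area exponent), and
hab_cur ≡ 1 (the current landscape is benchmarked as intact). The sums run
over a seeded uniform subsample of cells, default 20%; the same subsample
indexes numerator and denominator so that sampling error largely cancels —
the tests show the 20% estimate across 100 seeds agrees with full
enumeration to well within 2%. The ratio is clipped at 1 before
exponentiation: future similarity can exceed current similarity in cells
whose analogues become more widespread, and persistence cannot exceed 100%.

Regional persistence is the weighted geometric mean
P̄ = exp(Σ w_i ln max(p_i, ε) / Σ w_i) with floor ε = 1e−9 guarding
ln(0); sensitivity of P̄ to ε ∈ {1e−9, 1e−6, 1e−3} is reported on every
aggregate. Cell weights default to uniform — the appropriate weighting
(e.g. by modelled richness) is context-dependent, so weights are injectable
rather than guessed. Species heading for extinction is N = S·(1 − P̄),
reported unrounded and rounded to nearest. A geometric rather than
arithmetic mean is used because persistence values are proportional
quantities; the aggregate is correspondingly sensitive to near-zero cells,
which is the scientifically intended behaviour (losing a bioclimate
entirely matters more than uniform mild degradation).

Baseline (current-day) extinction debt is computed with unchanged climate
against the baseline land-use habitat map, so a degraded present landscape
yields a nonzero debt even before any climate change.

## Synthetic data: what it emulates, and what it does not

The generator produces the full input suite with known ground truth:

* **Landscapes**: smooth spatially autocorrelated fields (superposed
  low-frequency random harmonics plus noise) for two topographic variables
  (ruggedness derived from a generated elevation surface; wetness), one
  soil variable with a configurable missing fraction (default 10%,
  gap-filled by inverse-distance weighting, power 2, all observed cells as
  neighbours), and seven climate variables with realistic means and
  spreads. Potential evapotranspiration of the driest month has no
  derivation from the other variables and is treated as one more smooth
  climate field.
* **Communities**: each species has a product-Gaussian niche over a random
  subset of three variables (optimum within ±1.5 sd of the landscape mean,
  tolerance 0.5–1.5 sd, maximum occupancy 0.6–0.95). True occupancy is a
  deterministic function of (seed, species, environment) — identical cells
  host identical true assemblages — and yearly observation applies a
  per-species detection probability (default 0.8 over 3 survey years).
  Jaccard dissimilarity therefore rises with environmental separation, the
  property the dissimilarity model must recover.
* **Future climates**: additive per-decade trends per variable (static
  variables untouched), evaluated at slice midpoints. Severity scalars of
  0.2 and 1.0 for the mild and severe default scenarios give per-decade
  warming of about 0.1 and 0.5 °C respectively — bracketing low- and
  high-emission trajectories at the scale of the synthetic landscape.
* **Land use**: per-cell Markov chains over seven harmonised classes with
  a mild-intensification default matrix (2% per step conversion toward
  intensive classes, 0.5% urbanisation, urban absorbing).
* **Impact database**: multi-study site × species abundance tables where a
  class-c site keeps fraction s_c of its abundance on the reference species
  set and scales totals by a_c, making the balanced Bray–Curtis similarity
  to reference s_c and the abundance ratio a_c by construction (plus 5%
  lognormal noise); NPP is elevated at agricultural sites and effort varies
  uniformly on [0.5, 2]. Default truth spans BII 0.33–1.0 across classes.

What passing tests on these data do **not** show: real survey data have
spatially structured detection failure, observer effects, and temporal
autocorrelation the generator omits; real climate change is not a uniform
additive trend; real land-use transitions are driven by economics and
policy, not a stationary Markov chain; and the real impact database is
highly unbalanced across studies and biomes. Results on synthetic data
validate the estimators' correctness, not the magnitude of any real-world
projection.

## Problem sizes and numerical choices

Default test and acceptance scales: 20 × 20 landscapes (400 cells), 80
species, 3 survey years, 3000 site pairs, 30-study impact tables, 100
subsample seeds. These sizes keep every estimator in its asymptotically
well-behaved regime while the full suite runs in seconds on one CPU.

Numerical conventions collected in one place: dissimilarities clamped to
[1e−6, 1−1e−6] inside deviance; NNLS convergence at relative objective
change 1e−8, 200 iterations max; I-spline evaluation clamps inputs to the
knot span; persistence ratio clipped at 1; geometric-mean floor 1e−9;
precipitation seasonality uses the population standard deviation × 100 /
mean (the bio15 convention) and is flagged missing when mean precipitation
is zero; ruggedness at edge cells averages over existing neighbours only.

## Known limitations

* The GDM uses environment-only predictors; geographic distance as a
  predictor, variable selection, and bootstrapped coefficient uncertainty
  are out of scope.
* Space-for-time substitution is assumed, with clamped extrapolation
  outside training gradients.
* The extinction-debt method gives no timing: it counts species committed
  to eventual regional loss under the projected conditions, not when the
  debt is paid.
* Grid geometry is a unit-square lattice with trivial affine metadata;
  no CRS handling. Raster output is plain TIFF (one band per variable)
  with a JSON sidecar, alongside long-format CSV tables.
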