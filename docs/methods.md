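# Methods

## The model

Responses are polytomous Rasch (partial credit) observations: person *v*
with location θ_v (logits) answers item *i* with ordered categories
0..m_i via

    P(X_vi = x) ∝ exp( Σ_{k≤x} (θ_v − β_ik) ),    empty sum = 0,

where β_i1..β_im are the item's uncentered thresholds — the points on the
latent continuum where adjacent categories are equally likely.  The item
location is δ_i = mean_k β_ik and the centered thresholds τ_ik = β_ik − δ_i
sum to zero within item.  The raw total score is sufficient for θ_v, which
is what makes Rasch measurement "person-free": item comparisons do not
depend on the person distribution in the sample.

## Estimation

**Items — conditional maximum likelihood (CML).**  Conditioning on each
person's total removes θ from the likelihood.  The conditional likelihood
is evaluated with polytomous elementary symmetric functions computed by the
summation algorithm (successive polynomial convolution of the per-item
category weight vectors, each max-normalised for numerical range), and is a
concave exponential family in the thresholds; it is maximised by
Newton–Raphson with analytic gradient and Hessian and step halving.  The
Hessian is the negative sum of conditional covariance matrices of the
threshold-indicator statistics, assembled from leave-one-out and
leave-two-out symmetric functions.  The likelihood is invariant to adding a
constant to all thresholds, so the Newton step is solved on the Hessian
regularised along that null direction, and the solution is re-centered to
mean item location zero.  Convergence: gradient ∞-norm < 1e-8, at most 200
iterations; the step-halving acceptance slack scales with |log L| so the
quadratic convergence phase is not derailed by floating-point noise.
Standard errors come from the pseudo-inverse of the negative Hessian.
A score level never observed for an item (null category) makes the
corresponding threshold inestimable and raises a named error.

CML agrees with an independent brute-force conditional-likelihood
maximiser (full pattern enumeration) to 1e-4 on small instances, and item
estimates are invariant to the generating person distribution — both are
asserted in the test suite.

**Persons.**  Given anchored items, the ML estimate per raw total solves
Σ_i E_i(θ) = r by Newton (the left side is strictly increasing); persons
are mapped through this score table, which guarantees sufficiency (equal
totals → identical estimates) exactly.  SE = 1/√(test information at θ̂).
Extreme totals (0 and max) have no finite ML estimate; they are moved
inward by `extreme_adjust` = 0.3 score units before solving, giving finite
endpoint estimates.  The constant is configurable; the extrapolation used
by the commercial package that popularised these analyses is unpublished,
so no numerical equality with it is claimed.

## Fit diagnostics

Standardized residuals z_vi = (x_vi − E_vi)/√W_vi are computed at each
(non-extreme) person's estimate.  Because θ̂_v is estimated from the same
responses, residuals sum to zero within person, and E[z²] < 1.

* **Item fit residual.**  The column sum Σ_v z²_vi is carried to an
  approximately N(0,1) scale by the Wilson–Hilferty cube-root transform.
  The reference df is the variance-adjusted count
  df_i = Σ_v (1 − W_vi / Σ_j W_vj) rather than the raw person count:
  with the raw count the null mean sits near −1.4 (the person-estimation
  constraint absorbs one df per person), violating the mean-0/SD-1
  expectation the ±2.5 screening band assumes.  With the adjustment the
  null mean is ≈ 0.3 and SD ≈ 0.9 (simulation).  Person fit residuals use
  df = I − 1 for the same reason.  This is an approximation to the
  commercial implementation's unpublished transform, not an equality.
* **Item-trait χ².**  Persons are ranked by θ̂ and split into G
  equal-count class intervals (default G = min(10, n/50), ties broken by
  stable order); χ²_i = Σ_g (Σ_{v∈g}(x_vi − E_vi))²/Σ_{v∈g} W_vi with
  df = G−1; the total statistic sums over items.  Per-item p values are
  Bonferroni-compared at α = 0.01 divided by the number of items in the
  current analysis (one family per analysis step).  Under the null the
  total/df ratio runs ≈ 0.8–0.9 — slightly conservative, again because of
  the within-person residual constraint.
* **Residual correlations.**  Pearson correlations of residual columns;
  the local-dependency critical value is the average off-diagonal
  correlation + 0.2.  Under unidimensionality the average is ≈ −1/(k−1),
  so the critical value falls with scale length (≈ 0.15 at k=19, 0.13 at
  k=14, 0.12 at k=13), matching the values reported in applied work.
* **Threshold ordering.**  Strict increase of β_i1..β_im.
* **PSI.**  Person separation index (Var(θ̂) − mean SE²)/Var(θ̂) over
  non-extreme persons; the Rasch analogue of coefficient alpha.

## Unidimensionality (Smith's test)

PC1 of the residual correlation matrix (numpy eigendecomposition, sign
fixed for determinism) splits items into positively and negatively loading
subsets (|loading| ≥ 0.05).  Each person is re-estimated on both subsets
with item parameters anchored from the full fit, so both estimates share
one metric; persons extreme on either subset are excluded.  The statistic
t_v = (θ̂_A − θ̂_B)/√(SE_A² + SE_B²) is referred to ±1.96, and the scale
passes when the exact (Clopper–Pearson) 95% CI lower bound of the
significant share is below 5%.

Calibration note: with the subsets fixed a priori, t_v is well calibrated
(simulated SD ≈ 0.97).  The PCA step, however, picks the split that
maximises residual contrast, so under the null the significant share runs
≈ 5–7% rather than 5%; the CI-lower-bound decision rule absorbs most of
this.  On strictly unidimensional data (n=800, 12 items, θ~N(0,1)) the
median lower bound over seeds is ≈ 4%.

## DIF

Per item, a two-way fixed-effects ANOVA of z on a person factor and the
class intervals: the factor main effect is uniform DIF, the interaction
non-uniform DIF.  Type II sums of squares are used (the design is mildly
unbalanced; the choice is logged here because no convention is universal).
Bonferroni across items × factors at family α = 0.01.  Age enters
dichotomised at the sample median, ties to the lower group.

**Artificial DIF.**  One truly DIF item biases the person estimates and
can induce apparent DIF elsewhere.  The item with the highest flagged
uniform-DIF F is "split": its thresholds are re-estimated separately per
factor level with every other item anchored, putting the group-specific
locations on the common metric; their difference is z-tested with the CML
standard errors.  Residuals are recomputed with the group-specific
parameters and the remaining items re-tested; flags that disappear were
artificial.  Resolving with nothing flagged is a no-op.

## Testlets and latent structure

Locally dependent subscale items are summed into subscale super-items
(testlets) and the testlet-level matrix is re-fitted as an ordinary PCM.
Testlet score levels never observed are collapsed onto consecutive
observed levels (logged) — unavoidable when 9+ category super-items meet
n=800.  Subscale-level structure: each subscale is fitted and scored
separately; reliabilities are subscale PSIs; latent correlations are
disattenuated observed correlations capped at 1.  Explained common
variance uses the operationalisation

    t_k = ρ_k·Var(θ̂_k),  common = c̄·(Σ_k √t_k)²,
    total = Σ_k t_k + Σ_{k≠l} r_kl √(t_k t_l),  ECV = common/total,

which is 1 when all latent correlations are 1 and 0 under independence;
the literature the procedure stems from does not print a formula, so this
is a documented design choice, validated by its limiting behaviour in
simulation (tolerance 0.05).

## Score conversion

For a fitted instrument, one row per raw total: ordinal raw mean
1 + 4·total/max_total (step 1/I for I full-range items; 49 rows for 12
five-category items), the total's Rasch logit, and the interval metric
M = 1 + 4(θ − θ_min)/(θ_max − θ_min) anchored at the extrapolated
extreme-score estimates — so the anchors are data-dependent, as in
published conversion tables.  Serialized output rounds to 2 decimals
(half away from zero); full precision is kept internally.  Conversion of
raw means requires complete responses and on-grid values (snap tolerance
1e-9); anything else is an error naming the person — no imputation.

## Shortening pipeline

Steps proceed while any subscale exceeds `min_items` (default 3): at each
step every active subscale loses exactly its top-ranked candidate, scored
by the count of fired indicators (|FR| > 2.5, significant χ², DIF flag,
residual-correlation flag, adverse content category 3/4), ties broken by
residual-correlation excess, then smallest location gap to a retained item
(redundancy), then stable item order; protected items are down-weighted by
a configurable constant.  With subscale sizes (8,5,5,5) and minimum 3 this
yields the six analyses with roster sizes 23, 19, 15, 14, 13, 12.  On an
exact tie between a subscale's top two candidates, both one-item-removed
branches are refitted and compared on total χ², then location spread.
A testlet-level analysis of the final roster is appended.  The pipeline is
deterministic given data and configuration and emits a machine-readable
rationale per removal; it automates the *procedure*, not the expert
deliberation, which enters only through the content/protection
configuration.

## Synthetic data

The generator emulates a four-subscale burnout questionnaire: 23 items
(EX 8, MD 5, CI 5, EI 5), five categories, person effect = general factor
(default mean −1.04, SD 1.045, the reported targeting offset of the real
survey) plus subscale-specific nuisance factors (SD 0.6, giving
inter-subscale latent correlations near 0.7 and the within-subscale
residual-correlation signature that motivates testlets), item locations
staggered so EX items sit lowest and EI highest, and gender × country
strata (¼ each) with an age covariate (N(41, 11), matching the median-41
split).  Generating thresholds are equally spaced and ordered
(−2.0, −0.7, 0.5, 1.15 around each location); the top threshold was chosen
at design time so that, with the off-target person distribution, every
item's highest category is still comfortably observed at n=800 — the
complete-category precondition of CML.  DIF is injected as a location
shift (uniform) or a group-specific slope on θ (non-uniform) with known
ground truth.  Stratified subsampling draws exactly k per stratum without
replacement, reproducibly by seed.

What the generator does **not** emulate: the real data's skew beyond the
mean offset, item-specific wording effects, response styles, or
missingness (the pipeline is complete-case by contract).  Passing tests
therefore demonstrate that the machinery recovers known structure under a
bifactor-style dependency mechanism, not that any particular real
instrument behaves this way.

## Problem sizes and numerical choices

Simulation-based tests use n = 400–2000 persons and 3–10 seeds per
property — large enough that the asserted envelopes (e.g. RMSE(δ̂) < 0.1
at n = 2000; χ²/df in (0.7, 1.4); DIF power ≥ 0.8 at a 0.5-logit shift,
n = 800) are stable across reruns, chosen as the package's own test scale.
Person-solve tolerance 1e-10 on the score equation with Newton steps
clipped to ±2 logits; probability computations subtract the kernel max
before exponentiating; conversion-table rounding is half away from zero.

## Known limitations

* CML, not the pairwise-conditional estimator of the commercial package;
  estimates share the invariance property but are not numerically
  identical to published outputs, and the fit-residual transform is an
  approximation (see above).
* The ECV formula is an operationalisation (see above).
* Smith's test inherits the PCA selection effect; its null rate is ≈ 5–7%,
  not exactly 5%.
* Subscale reliabilities from 3-item subscales are low (≈ 0.5–0.65), so
  disattenuated correlations are noisy and occasionally cap at 1.
* No missing-data support by design; incomplete rows are dropped at I/O
  with a logged count.
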