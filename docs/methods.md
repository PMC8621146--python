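# Methods

## The bivariate binomial-normal model

Each study contributes a 2×2 table: `tp` of `n_dis = tp + fn` diseased
subjects test positive, `tn` of `n_con = fp + tn` controls test negative.
The model places the study's true operating point on the logit scale,

    tp_k ~ Binomial(n_dis_k, expit(theta_k1)),
    tn_k ~ Binomial(n_con_k, expit(theta_k2)),
    (theta_k1, theta_k2) ~ N2(mu, Sigma),

and maximises the marginal likelihood over `mu` (mean logit-Se, mean
logit-Sp) and the between-study covariance `Sigma`.  Using the exact
binomial within-study likelihood (rather than approximating observed logits
as normal with known variance) keeps studies with Se or Sp equal to 1 in
the model and needs no continuity correction inside the likelihood; this is
the standard GLMM formulation of bivariate DTA pooling.

**Quadrature.** The 2-D integral per study is evaluated by *adaptive*
Gauss–Hermite product quadrature: a damped Newton iteration (vectorised
across studies) finds each study's integrand mode and curvature, the
product rule is recentred and rescaled there, and the sum is accumulated in
log space.  Default 15 nodes per dimension; with adaptive recentring the
log-likelihood is stable to well below 1e−7 beyond ~15 nodes, and the test
suite checks agreement with dense 2-D Simpson integration to 1e−6 on small
examples.  Near-degenerate `Sigma` (an eigenvalue below 1e−10) receives a
ridge of that size so the likelihood stays defined as an optimizer
approaches the boundary.

**Optimisation.** `Sigma` is parameterised unconstrained as
`(log sd1, log sd2, atanh rho)`.  Starts come from the empirical logits
(0.5-corrected); each restart perturbs the start with seeded Gaussian
noise.  Each restart runs L-BFGS-B (finite-difference gradients) followed
by a short Nelder–Mead polish; the best of `restarts` (default 5) is kept.
Non-convergence is reported via `converged=False`, never raised.
`vcov(mu)` is the `mu` block of the inverse of a central-difference Hessian
of the full 5-parameter log-likelihood at the optimum, eigenvalue-clipped
to be positive semi-definite.

**Summaries.** Pooled Se/Sp are `expit(mu)` with Wald intervals on the
logit scale.  PLR, NLR and DOR use the delta method on the log scale with
gradients `(1−se, sp)`, `(−se, −(1−sp))` and `(1, 1)` with respect to
`mu`; `dor = plr/nlr` holds exactly at the point estimates.

**SROC.** The curve is the regression line implied by the fitted
covariance, `logit(se) = mu1 + (Sigma12/Sigma22)(logit(sp) − mu2)`, traced
over the observed false-positive-rate range (always extended through the
summary point) and mapped to ROC space.  The 95% confidence region is the
Wald ellipse of `mu` (chi-square(2) quantile) and the prediction region
uses `vcov(mu) + Sigma`; both are sampled as polygons and mapped pointwise.
This regression-through-covariance construction is one of several SROC
definitions in the literature; alternatives (e.g. the Rutter–Gatsonis
HSROC curve) are out of scope.  Note the construction is direction-specific
(it regresses logit-Se on logit-Sp), so the traced curve is *not* symmetric
about the Se = Sp diagonal even for exchangeable parameters — reflecting it
would give the conjugate regression line with reciprocal slope.  When
`Sigma22 = 0` the curve is degenerate and a dedicated error points the user
to the summary point.

## FRI

`FRI = Nf × Pmax`: the number of independent facial phenotypes times the
maximum penetrance among all of a disease's facial phenotypes (a fraction
in (0, 1]; files carry percent).  Correlated phenotypes share a
`group_id` and count once in `Nf`; `Pmax` is deliberately taken over all
phenotypes, not one representative per group — with the packaged reference
data the two readings coincide, and the all-phenotype reading is the
simpler contract.  A phenotype definitional for a patient group has
penetrance 1.

The packaged seven-disease table reproduces the published FRI values
{9, 8, 7.443, 6, 5, 4, 3.36}.  Two caveats it surfaces explicitly:

* **Angelman syndrome** is internally inconsistent in its source: the
  reference table prints Nf = 6, Pmax = 100%, FRI = 6, while the
  accompanying text says "FRI of 8".  The package follows the table and
  `load_reference_phenotypes` emits a `PublishedValueWarning` every time.
* Per-phenotype penetrances below each disease's maximum are not published;
  the fixture assigns `Pmax` to every phenotype of a disease.  This is a
  synthetic detail that leaves `Nf`, `Pmax` and FRI exact.

## Meta-regression and threshold inversion

Per-study `ln(OR)` comes from the 2×2 table with Woolf variance
(sum of reciprocal cells); 0.5 is added to *all four* cells if and only if
some cell is zero, for `ln(OR)` and its variance only — observed Se/Sp and
their Clopper–Pearson intervals always use raw counts.  The random-effects
regression

    y_k = x_k' beta + u_k + e_k,   u_k ~ N(0, tau2),   e_k ~ N(0, v_k known)

estimates `tau2` by REML (bounded 1-D maximisation of the restricted
likelihood, tolerance 1e−10, with an explicit check of the `tau2 = 0`
boundary) or by the DerSimonian–Laird moment estimator; inference on
coefficients is Wald-z at the estimated `tau2`.  A saturated design
(n = p) fixes `tau2 = 0`.  Studies entering the FRI regression are by
default those mapped to a single scored disease; multi-disease studies have
no defined FRI and are excluded (configurable).

Inverting the fitted line at a target (Se, Sp) gives
`OR = Se·Sp/((1−Se)(1−Sp))`, `ln OR`, and
`FRI_required = (ln OR − intercept)/slope`.  Full precision is kept
internally; presentation rounds half-up to 2 decimals.

**Published coefficient sets.** Two variants of the reference line are
exposed: `EQ2_COEFFS = (0.4960, 1.459)` (the equation as printed) and
`TABLE3_CAPTION_COEFFS = (0.4951, 1.46)` (the variant printed beside the
published threshold table).  Neither reproduces every cell of that table at
2 decimals: with (0.4960, 1.459) the (Se, Sp) = (0.90, 0.85) row gives
`(ln 51 − 1.459)/0.4960 = 4.9855 → 4.99` against a printed 4.98, and the
caption pair misses three cells.  The one pair consistent with all five
printed FRI cells is slope 0.4960 with intercept 1.46.  The package
computes honestly from whichever coefficients it is given and does not
special-case the discrepant cell.  (The published source also reports the
FRI coefficient of the two-covariate model differently in its text, 0.4868,
and its table, 0.4939; both are simply estimates the user can reproduce on
their own data, and neither is hard-coded.)

**Subgroups.** Each subgroup with ≥ 2 studies is pooled with the bivariate
model; singleton groups are reported with raw proportions, flagged
degenerate, and excluded from the interaction test.  The interaction
p-value is a Wald test on the group-indicator block in a `ln(OR)`
meta-regression — a z-test for binary splits, a chi-square block test for
multi-level ones.  No multiplicity correction is applied across subgroup
variables.

## Synthetic data

`simulate_studies` draws latent logits from `N2(mu, Sigma)`, arm sizes
uniformly from 17–242 subjects per arm (the testing-set range observed in
the facial-recognition diagnostic literature this package targets), and
binomial counts.  Defaults centre on the reference operating point
(Se 0.89, Sp 0.92) with `Sigma = diag(0.5, 0.5)`.

`simulate_fri_cohort` adds the generative accuracy/FRI link: each study
draws FRI uniformly from a value set (default: the seven reference FRI
values), sets `ln DOR = slope·FRI + intercept + N(0, tau²)`, anchors
specificity (default 0.92, configurable) and gives the remainder of the
log-DOR to sensitivity, since `ln DOR = logit Se + logit Sp`.  The
anchor-and-remainder split is a modelling choice — a DOR alone does not fix
the (Se, Sp) decomposition.  Implied sensitivities outside (0, 1) are
resampled (at most 100 attempts, then a hard error); with the default
parameters this never triggers.  All randomness flows through one
`numpy` generator seeded from the config, so identical configs are
byte-identical.

What the generator does **not** emulate: correlated photographs across
studies sharing databases, covariate-dependent arm sizes, risk-of-bias
structure, or any image-level process.  Passing recovery tests therefore
demonstrates estimator correctness under the model's own assumptions, not
robustness to real-data violations of them.

## Orchestration

`run_full_analysis` executes read → FRI attach → forest → pool → SROC →
meta-regression → thresholds → subgroups → strata → sensitivity refits,
writes every artifact (JSON report plus CSV mirrors and a JSON-lines log
carrying seed and config hash per stage), and is deterministic given inputs
and config (timestamps aside).  A failing stage raises an error naming the
stage; artifacts of completed stages remain on disk.

Stratified accuracy reports median (min, max) of per-study Se/Sp by FRI
band crossed with training-set-size band and optionally model class.
Bands are right-open except the last interior band, which is closed:
cutpoints (100, 1000) mean `<100`, `[100, 1000]`, `>1000` — matching the
band labels conventional in this literature.  Medians use the standard
midpoint rule for even counts.  Empty strata are reported, not dropped.

## Problem sizes and numerical defaults in the test suite

The calibration tests run 200 seeded replicates of 20-study meta-analyses
(bivariate recovery: mean pooled Se within 0.02 of truth, Wald coverage in
[0.90, 0.98]) and 200 replicates of 60-study FRI cohorts (slope recovery
within 0.05, coverage ≥ 0.90).  These simulations use 7 quadrature nodes
and a single moment-started optimisation per fit — numerical settings
chosen for the replicate ladder; the statistical conditions (replicate
count, study counts, truth values, arm-size range) are the model's
reference conditions.  Oracle comparisons (dense Simpson integration,
closed-form WLS, the DerSimonian–Laird Q formula, Clopper–Pearson via an
independent implementation) pin the likelihood and estimators
independently of the code paths they check.

## Known limitations

* Wald intervals (logit scale for Se/Sp, log scale for ratios) can
  undercover slightly for very small study counts; the observed coverage at
  K = 20 sits near 0.92.
* REML `tau2` uses bounded scalar optimisation; pathological likelihood
  surfaces with multiple interior optima would be missed (none arise in the
  tested regimes).
* The SROC curve is the regression-through-covariance construction only.
* Exact reproduction of any externally published pooled numbers depends on
  that source's estimation defaults (software, quadrature, convergence
  rules), which are rarely reported; the package documents its own.
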