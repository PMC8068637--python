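# Methods

## The model

`shiftsem` analyses longitudinal patient-reported-outcome (PRO) data with a
longitudinal confirmatory factor model.  For P continuous indicators
observed on the same persons at T occasions, the stacked PT-vector of
observations has the covariance and mean structure

    Sigma = Lambda Phi Lambda' + Theta        mu = tau + Lambda kappa

where `Lambda` (PT x QT) is block-diagonal over occasions and holds the
factor loadings, `Phi` (QT x QT) holds the factor variances and covariances
within and across occasions (the cross-occasion block is always fully free),
`Theta` (PT x PT) holds residual variances — diagonal within occasions, with
cross-occasion covariances only between the residuals of the same indicator,
representing indicator-specific stable variance — `tau` the intercepts and
`kappa` the common-factor means.  Estimation is normal-theory maximum
likelihood on the sample covariance matrix (denominator n−1) and mean
vector; the test statistic is (n−1) times the minimized discrepancy.

Identification is by standardized factors: every occasion's factor variances
are fixed to 1 and factor means to 0 when each occasion's parameters are
free (the measurement model), and only the first occasion's once
across-occasion equality constraints let the follow-up variances and means
be estimated.  Scaling by unit factor variance rather than by a marker
loading keeps all loadings on a comparable metric across occasions, which is
what the invariance tests compare.

## Response shift as measurement non-invariance

Change over time in what a self-report instrument measures ("response
shift") appears statistically as non-invariance of measurement parameters:

* **recalibration** — an indicator's intercept differs across occasions
  (the same latent state maps to different scores);
* **reprioritization** — an indicator's loading value differs (the
  indicator's importance to the construct changed);
* **reconceptualization** — the loading *pattern* differs (an indicator
  joins or leaves a construct).

"True" change is change in the common-factor means after accounting for
detected shifts.

## The four-step procedure

1. **Measurement model.**  The configured factor structure is fitted jointly
   to all occasions.  If overall fit is inadequate (RMSEA at or above 0.08
   by default), modification candidates (within-occasion residual
   covariances and cross-loadings) are ranked by score-test modification
   indices; with `auto_modify` the top candidate is freed, at most
   `max_modifications` (3) times.  Modifications are never applied silently.
2. **Omnibus invariance test.**  All loadings and intercepts are constrained
   equal over occasions; the likelihood-ratio test against Step 1 (df
   difference 2P−2Q for the canonical two-occasion model) is the gate that
   protects against false-positive shift detection.  Only a significant
   deterioration (default alpha 0.05) opens the search.
3. **Specification search.**  All remaining loading equalities, intercept
   equalities and (optionally) pattern-zero follow-up loadings are released
   one at a time and each candidate model refitted; the candidate with the
   largest significant chi-square(1) improvement is incorporated and
   classified by the shift taxonomy above.  The likelihood-ratio statistic
   from an actual refit is used as the selection criterion; modification
   indices serve only to pre-screen when the candidate set is large (more
   than 24 candidates; the top 12 are refitted).  Stopping (default) requires
   both that no candidate is individually significant and that the current
   model no longer differs significantly from the measurement model; either
   condition alone can be selected (`stop_rule`).  A freed
   reconceptualization loading that is not significant by Wald test is
   rolled back.
4. **True change.**  The follow-up factor means of the final model (baseline
   fixed at 0) are reported with standard errors and Wald tests, next to the
   same quantities from the Step-2 model; their difference is the impact of
   response shift on the change estimate.

Observed model-implied mean change is decomposed exactly as

    mu2 − mu1 = (tau2 − tau1)  +  (Lambda2 − Lambda1) kappa_w  +  Lambda_w (kappa2 − kappa1)

i.e. recalibration + pattern/value shift + true change.  The default
("baseline") convention weights true change by the baseline loadings
(`Lambda_w = Lambda1`) and the loading-shift term by the follow-up factor
means (`kappa_w = kappa2`); the mirrored ("followup") convention is
available by option because the weighting is a genuine convention choice —
either way the three components sum to the implied change identically, which
the test suite asserts at 1e-10 on random admissible models.  Effect sizes
divide latent change by the baseline factor SD (1 by identification) and
indicator components by the baseline observed SD, labelled with the
conventional 0.2/0.5/0.8 bands.

## Ties and alternative sequences

Sequential specification search is order-dependent: near-equivalent releases
are common, and a purely statistical choice between them is arbitrary.
Candidates whose improvement lies within `tie_tolerance` (0.5 chi-square
units) of the best are recorded as a tie in the search trace; the
deterministic default choice prefers intercepts over loadings and then
indicator declaration order.  `explore_sequences` forks the search at every
tie (up to `max_branches` = 8) and tabulates how often each finding recurs
across branches — recurrent findings are robust to sequencing, sporadic ones
are not.  The choice among tied alternatives ultimately requires substantive
judgment; the report says so explicitly.

## Identifiability guard

Releasing invariance constraints without limit destroys identification: if
every intercept of a factor's indicators is freed along with the follow-up
factor mean, the model is singular.  The search therefore never offers a
release that would leave a factor without at least one invariant loading
(anchoring the follow-up factor scale) or one invariant intercept (anchoring
the follow-up factor mean).  A consequence worth knowing: a uniform
intercept shift on *all* indicators of a factor is empirically
indistinguishable from latent change, and shifts proportional to the
loadings are exactly latent change.  Equal same-sign shifts on a subset of
indicators can likewise admit an equivalent, more parsimonious explanation
(one opposite shift on the complementary indicator plus latent change) that
the greedy search will rightly prefer.  Detection is only well-posed for
shift configurations that are not absorbable this way — one more reason the
procedure's output needs substantive review.

## Estimation details

* Parameters are addressed by name (matrix, indicator/factor, occasion), and
  across-occasion equalities are equality groups estimated as a single
  underlying parameter, so group members are exactly identical after
  fitting.
* Optimization: L-BFGS-B with analytic gradients, box bounds keeping
  variance parameters above 1e-6, followed by Newton polishing with a
  finite-difference Hessian of the analytic gradient until the projected
  gradient max-norm is below 1e-6; up to 5 jittered restarts on failure.
  Non-positive-definite implied covariances act as a barrier.  An
  unconverged fit is returned flagged, without standard errors.
* Starting values: loadings 0.7, factor covariances 0.3, free factor
  variances 1, residual variances half the observed variances, intercepts at
  the sample means, free factor means 0; warm starts reuse the incumbent
  model's estimates throughout the procedure, which is what makes the
  candidate refits in the search cheap.
* Standard errors: inverse observed information of (n−1)/2 times the
  discrepancy at the optimum.  Variance estimates at the lower bound are
  flagged as Heywood cases, not suppressed.
* Modification indices: score tests computed from the gradient of the
  candidate cell and the Schur complement of its Hessian block against the
  free parameters, with the expected parameter change `-s/h`.  The score
  approximation tracks the refitted likelihood-ratio statistic closely for
  mild misspecification and underestimates it for gross misspecification,
  which is why the search itself refits.
* Missing data: listwise deletion, with the dropped-row count reported.
  Full-information estimation is out of scope.

## Fit indices

Chi-square exact-fit test; RMSEA = sqrt(max(chi2 − df, 0)/(df (n−1))) with a
90% confidence interval from inverting the noncentral chi-square
distribution, labelled "close" below 0.05 and "reasonable" below 0.08
(strict inequalities); CFI (clamped to [0,1]) and TLI (reported raw, may
exceed 1) against the independence baseline with free variances and means;
ECVI in its AIC-rescaled form (chi2 + 2q)/(n−1), AIC = chi2 + 2q,
BIC = chi2 + q ln n.  Nested comparisons report the chi-square difference
test, the clamped-CFI difference against the 0.01 rule, and ECVI/AIC
differences signed so that positive values favour the less restricted
model; ECVI and AIC order any model pair identically by construction.  The
ECVI difference is descriptive (no significance machinery).

## The synthetic-data generator

The canonical generating model mirrors the worked example: three factors
(physical, mental, social health), three indicators each, two occasions.
Defaults: standardized loadings 0.8/0.7/0.6 within each triplet,
within-occasion factor correlations 0.3, cross-occasion factor correlations
0.5 (same factor) / 0.2 (different), residual variances 1 − loading², and
residual autocorrelation 0.2 for the same indicator across occasions — a
pattern typical of well-behaved PRO subscale data with test–retest
structure.  Shifts are injected on the follow-up side of the population
model (intercept offset, loading offset, or a loading in a pattern-zero
cell) and persons are drawn i.i.d. multivariate normal from the injected
model's implied moments, fully seeded.

What the generator does *not* emulate: item-level ordinal responses,
floor/ceiling effects, non-normality, informative missingness, attrition, or
person-level heterogeneity in shift.  Passing recovery tests therefore show
that the procedure identifies shifts under its own assumptions; they do not
certify behaviour on real questionnaire data, where those violations are the
norm.

## Study sizes used in tests and the acceptance script

Calibration and recovery are Monte-Carlo studies: the test suite uses 1000
replications at n=300 for the null calibration of the omnibus test and 200
replications at n=500 per shift scenario (injected magnitudes 0.5 intercept,
0.3 loading, 0.4 pattern loading); the acceptance script reports the same
quantities at 400 and 120 replications respectively, sizes chosen to keep
Monte-Carlo error small relative to the reported rates while the script
completes in a few minutes on one CPU.  Recovery is measured for the Step-3
search run unconditionally after Steps 1–2, so the search's hit rate is not
confounded with the omnibus gate's power, which is reported separately.
Recovered magnitudes are means over replications in which the top finding
matches the injection; such post-selection means carry a mild winner's-curse
inflation for effects near the detection threshold (visible for the 0.3
loading shift), discussed below.

## Known limitations

* Post-selection inflation: magnitudes of shifts retained by the search are
  conditionally biased away from zero when power is well below 1 — a
  property of any sequential specification search, not of the estimator
  (unconditional estimates from the correctly released model are unbiased
  within Monte-Carlo error).
* Equivalent models: shift configurations absorbable by factor means (see
  the identifiability guard section) cannot be distinguished from latent
  change by fit alone.
* Non-uniform recalibration (residual-variance non-invariance) is
  deliberately not tested: it does not affect factor-mean change, which is
  the quantity of interest here.
* Categorical indicators, multiple groups, explanatory covariates for
  detected shifts, robust corrections and FIML are out of scope.
* At T > 2 occasions, Step-2 equality constraints are imposed jointly
  across all occasions; pairwise alternatives are not implemented (the
  worked analyses are all T = 2).
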