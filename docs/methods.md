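# Methods

## The fusion-validity model

A researcher-constructed scale is modeled as a latent variable whose
*producing equation* is the arithmetic actually used to compute its scores:
for an average of k items, fixed effects w_i = 1/k from the observed items,
and no residual term, because nothing besides the items enters the
computation. The scale is then embedded in a structural model containing
the downstream variables it is theorized to affect and whatever exogenous
controls the theory requires. The baseline specification grants the scale
preferential treatment — only the scale carries item influence downstream —
and the assessment asks whether the data tolerate that restriction.

### Coordinate convention

Everything is latent ("all-y"): each observed variable is represented by a
proxy latent with loading 1.0 and zero indicator error, so the indicator
error matrix Θ_ε is identically zero and all fixed measurement-error
variances sit on the proxy latents' diagonal of Ψ. Scale items additionally
receive an indicatorless true-score latent tied to the observed item by a
fixed unit effect. This convention is what lets item measurement error flow
*into* the scale — real scale scores are computed from error-containing
items — while item true scores remain available as sources for
scale-bypassing effects. Because Θ_ε is never inverted, its rank deficiency
is a non-event internally. A `from_true_scores` switch moves the fixed
weights from the observed-item proxies to the true scores, yielding the
measurement-error-free scale variant useful for asking how a scale purified
of item error would behave.

Implied covariance: Σ(θ) = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + Θ_ε. Downstream and
control variables use single indicators with declared error fractions
(fraction × observed sample variance, frozen before optimization). The
fraction-of-observed-variance basis is the natural operationalization when
only percentages are declared.

### Free/fixed pattern and degrees of freedom

Free by default: all declared structural paths, the exogenous moments
(item true scores and control constructs covary freely within and across
blocks), and downstream disturbance variances. Fixed: weights, unit
measurement effects, error variances, and the scale residual (zero).
Reciprocal pairs without exclusions can be identified either by an equality
constraint on the two directions (one parameter, two loci) or by fixing one
direction at a small literature-based value; both devices are expressible
in the path declaration (`equal:` groups, `fixed:` values). df equals
p(p+1)/2 minus the number of free parameters; each amendment costs one.

## Estimation

Normal-theory ML: F(θ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p, minimized by Fisher
scoring — steps −(E + λI)⁻¹g with the expected information
E_kl = tr(Σ⁻¹ ∂Σ_k Σ⁻¹ ∂Σ_l), an analytic gradient g_k = tr[(Σ⁻¹ −
Σ⁻¹SΣ⁻¹)∂Σ_k], backtracking line search, and a Levenberg ridge that grows
only when a step fails. Trial points where Σ (or I−B) loses positive
definiteness return +∞ and are handled by step shrinkage, not failure.
Convergence: max|g| < 1e−6, with a relative-F fallback of 1e−9; these are
far tighter than the one-decimal χ² reporting convention. χ² = (N−1)·F_min
(the classic convention; an N multiplier is available), p-values from the
central χ² distribution, standard errors from (2/(N−1))E⁻¹ at θ̂ (observed
information by finite differences of the analytic gradient as an option).
Start values follow the indicatorless-latent recipe: exogenous moments
start at the corresponding observed moments (minus fixed error on
diagonals), disturbances at the full systematic variance, free effects at
0.05. Negative free variances at the optimum are flagged as Heywood cases,
never silently bounded. Missing data are out of scope: the input is a
complete covariance matrix.

## Diagnostics

Modification indices are univariate score tests using the *full* extended
information matrix: for candidate c with gradient g_c and Schur complement
S_c = E_cc − E_cf E_ff⁻¹ E_fc, MI = ½(N−1)g_c²/S_c and EPC = −g_c/S_c.
The full-information form (not the diagonal approximation) is what makes
MI ≈ the χ² drop an actual refit delivers — the property the test suite
verifies (within 15% for MI > 5; observed agreement is typically a few
percent). Candidates whose Schur complement is numerically zero are
unidentifiable if freed singly (e.g. the weight of a single-item scale) and
are excluded with a notice. The candidate ledger is deliberately restricted
to scale-confronting loci: item bypasses (k × m), causes of the scale
(controls and downstream variables), the scale residual variance, and the k
item weights, in deterministic lexicographic order.

Standardized residuals divide s_ij − σ̂_ij by its asymptotic error,
Var(s_ij) − Var(σ̂_ij) with Var(s_ij) = (σ_ii σ_jj + σ_ij²)/(N−1) and the
fitted part from the delta method. Moments the model reproduces exactly
(the item-by-item block, by construction — the free true-score moments
absorb the observed item moments regardless of the items' factor structure)
give 0/0 ratios and are reported as zero.

The amendment search is greedy and sequential: free the largest admissible
MI above 3.84, refit, stop when p ≥ α (default 0.05), the ledger is
exhausted, or a configured addition cap is hit. Admissibility hooks: EPC
sign filters, loop avoidance (default; `--allow-loops` enables loop-closing
candidates and then checks the spectral radius of B̂ each step), and an
interactive accept/reject callback — sign and magnitude *palatability* is a
theory judgment a program cannot automate, so the machine only flags.
Freed cause-of-scale loci mark the scale as redefined; every report then
renames it `New-<scale>`, because an added cause does not explain the
original scale, it changes what the scale is.

## Effects

An item's indirect effect on a downstream variable is the fixed product
1.0 × w_i × (scale→target direct coefficient) — identical across items for
an equal-weight scale, exactly (scale effect)/k. The decomposition table
uses the scale's *direct* coefficient in this product even when the scale
sits in a loop, because that is the quantity the fixed-weight arithmetic
composes with; loop-consistent totals (I−B̂)⁻¹−I are computed separately
and the two diverge when loops exist. Rows are tagged "supplementing"
(direct and indirect same-signed), "nullifying" (opposing direct, |total| ≤
half the indirect's magnitude — a display threshold, not an inferential
claim), or "reversing" (total changes sign). Standard errors for indirect
and total effects (delta method or bootstrap) are not provided.

## Synthetic data generator

Scenarios are built forward from a declarative spec plus true parameter
values; proxy error variances are solved so each observed variable carries
*exactly* its declared error fraction, which makes fitting the true model
to the implied Σ return the generating values with F = 0 (a property the
tests assert). Sampling draws raw multivariate-normal data (seeded
`numpy` Generator, Cholesky factor) and computes the unbiased sample
covariance, leaving room for future raw-data features; everything is
bit-reproducible given (seed, reps).

The mini topology — 3 items, 2 interrelated downstream variables, 2
controls, 5% error everywhere, true-score variances 1.0 with 0.3
covariances, scale effects 0.4/0.3, a 0.25 downstream interconnection,
0.2 control effects, disturbances 0.6 — mirrors the structural features of
a realistic validation layout (items → scale → correlated downstream,
controls covarying with the item true scores) at trivial cost: a fit takes
a few milliseconds, so the 500-replication calibration experiments run in
seconds. Misspecification magnitudes are standardized (bypass coefficient =
magnitude × sd(target)/sd(source) under the baseline truth; default 0.2) so
power is comparable across loci.

One identifiability fact shaped the extra-cause scenario: an unmodeled
cause of the scale leaves the item moments and item-by-downstream moments
untouched; its entire signature is excess covariation among the scale's
downstream variables. A free downstream→downstream path absorbs exactly
that excess, so with two downstream variables the residual diagnostic has
essentially one moment of evidence and little power. The extra-cause
scenario therefore runs on a three-downstream variant with no free
downstream interconnections, with an unmodeled input worth the scale's own
baseline variance — a scale that is genuinely half something else — which
the residual diagnostic then flags essentially always (positive EPC).

What the generator does *not* emulate: non-normal (e.g. Likert-discrete)
items, missing data, multi-group structure, or sampling of persons into
units. Passing tests therefore show the machinery is correct and calibrated
under multivariate normality at the declared error fractions, not that any
real instrument is valid.

## The Leadership worked example

The packaged layout reproduces the published structure of the Alberta
Context Tool Leadership assessment: 6 averaged items (weights exactly 1/6,
displayed as 0.167), 7 downstream variables, 6 controls, three reciprocal
downstream pairs (one identified by exclusions, two by equality
constraints — the equality-constrained pairs are what make the baseline df
come out at 67, amended 61, and 68 for the variant fixing one direction at
−0.150). The shipped covariance matrix is **synthetic** — generated from
the amended-model coefficient point values plus invented exogenous moments
(unit true-score variances, 0.5 inter-item covariances, 0.1 elsewhere, 0.6
disturbances) — because the original raw covariance data are not
distributed with the package. It exercises the identical structure
(fitting the amended model to it recovers the generating coefficients with
F = 0) but deliberately cannot reproduce published χ² magnitudes, which
depend on the real data.

## Numerical choices and limitations

* Weights are exact rationals (1/k) internally; reports round to 3 decimals.
* Ties in candidate ordering break lexicographically by (source, target);
  the greedy trace is deterministic given a fit and policy.
* The p-value of a saturated model (df = 0) is reported as 1.0.
* Non-PD input covariance matrices are flagged and carried as warnings, not
  rejected; genuinely unusable inputs fail in the first line search.
* Equality constraints are supported only as shared loci of one parameter
  (sufficient for reciprocal-pair identification); general linear
  constraints are not.
* Multi-indicator downstream constructs, WLS/robust estimators, mean
  structures, multi-group and Bayesian estimation are out of scope.
  Factor-plus-fusion comparisons are possible as two independent fits, but
  no automated nested-test helper is provided.
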