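# Methods

## The moment model

The analytic chain treats three zero-mean jointly normal quantities: the
standardized outcome or liability `Y`, the environmental score `X`, and
the estimated polygenic score `Ŝ`.  All accuracy metrics are functions of
second moments only, which is what makes desk-scale projection possible.

**Polygenic score moments.**  Markers are independent and standardized;
effects follow a normal-null mixture (`π₀` null, the rest
`N(0, R²GY/((1−π₀)m))`).  Marginal OLS estimation in a training sample of
size `n` adds noise of variance `1/n` (continuous) or `P(1−P)/n` on the
observed 0/1 scale (binary, case fraction `P`).  Selecting markers whose
two-sided P-value falls in `(p0, p1]` turns the expected moments into
truncated second-moment integrals

    T(x0, x1) = Φ(x0) − Φ(x1) + x1·φ(x1) − x0·φ(x0) = ∫_{x1}^{x0} z²φ(z) dz

evaluated at the raw selection quantiles `q_j = Φ⁻¹(1 − p_j/2)` for null
markers and at the shrunken quantiles `r_j = q_j·θ` for informative ones,
where `θ = (n_eff·σ²_eff/((1−π₀)m) + 1)^(−1/2)` with
`n_eff = n, σ²_eff = R²GY` (continuous) or `n_eff = n/(P(1−P))`,
`σ²_eff = c²R²GY` (binary).  The factor 2 throughout accounts for the two
tails.  Binary-trait effects are estimated on the observed scale and
mapped to liability with `c = φ(τ)P(1−P)/(K(1−K))`, which reduces to
`φ(τ)` in a prospective design.

**Infinite training samples** are an explicit code path, not a large-`n`
surrogate: `θ = 0` exactly, an open window (`p0 = 0`) retains every
informative marker (`r0 = ∞`, `r1 = 0`, `T = 1/2`), and the polygenic R²
equals the chip heritability.  Infinite quantiles are honest `math.inf`
sentinels; `Φ(∞) = 1` and `∞·φ(∞) = 0` are evaluated as limits.

**Combination and calibration.**  `Ŝcomb = w1Ŝ + w2X` with unit weights or
the closed-form (Cramer) least-squares solution of the 2×2 normal
equations; a determinant below 1e−12 triggers an explicit fallback to the
environment-only score with a warning.  The calibration coefficient
`γ = cov(Ŝcomb,Y)/var(Ŝcomb)` rescales the combined score so its variance
equals its liability R²; the least-squares weights give `γ = 1`
identically, which the suite asserts to 1e−9.

## Metrics

Conditioning the score on case/control status gives closed-form moments
(truncated-normal algebra); the conditional distributions are treated as
normal.  This is an approximation — the exact conditional law of a score
given `Y > τ` is skewed — and the Monte Carlo simulator quantifies rather
than replaces it: at the reduced scales used in the tests the bias is
below the Monte Carlo resolution (3 SEs over 100 replicates).

* AUC: `Φ((E₁−E₀)/√(V₁+V₀))`.
* Case capture: share of cases above the top-`q` population threshold
  `√r²·Φ⁻¹(1−q)` of the calibrated score.
* Sensitivity/specificity at absolute risk `a`: tail probabilities of the
  conditional normals at the score cutoff `τ − √(1−r²)·Φ⁻¹(1−a)`.
* Categorical NRI: differences of trivariate-normal rectangle
  probabilities of `(Y, X, γŜcomb)` across the risk cutoffs of the two
  scores.  Rectangles are evaluated by the quasi–Monte Carlo
  multivariate-normal CDF (scipy's Genz-style integrator) at absolute
  tolerance 1e−7 with a fixed internal QMC seed, so results are
  deterministic across calls; probabilities are clipped to [0, 1].
* Continuous NRI: orthant probabilities of the bivariate normal of
  `(Y, γŜcomb − X)`.  A degenerate difference score
  (`var(γŜcomb − X) ≤ 1e−14`) is defined as (0, 0): no reclassification.
* IDI: adaptive quadrature (scipy `quad`) of
  `Φ((τ−s)/√(1−r²))·(φ₀(s) − φ₁(s))` over ±8 conditional SDs, which is
  where the integrand exceeds double-precision noise; the test suite
  cross-checks the quadrature against the closed form
  `1 − Φ((τ−m)/√(1−r²+v))` that the integral collapses to.

## Design inversions

`optimize_threshold` maximizes any metric over `p1` on a 200-point
log-spaced grid (1e−10…1) refined by bounded golden-section search in
log10 p1 to 1e−3, ties toward smaller `p1`.  `required_sample_size`
checks the `n = ∞` limit first (raising with the limit named if the
target is unattainable), then bisects on log10 n to three significant
figures, optionally re-optimizing `p1` at every `n`; the result is
rounded *up* so the returned size still meets the target.

**Family history as the environmental score.**  For a trait with total
heritability `h²` and chip heritability `h²c`, the mid-parent phenotype,
rescaled by `h²` to have unit effect on the offspring, explains
`R²XY = h⁴/2` of the offspring variance (0.32 at `h² = 0.8`).  Writing
the predictor's covariance with the offspring's own chip genotypes shows
that the offspring markers explain `h²c/2` of the predictor's variance
(`R²GX = h²c/2`) and that the per-marker effects on the predictor are
exactly proportional to the chip effects on the outcome, so the effect
correlation is `ρ = 1` — the mid-parent–offspring *genetic-value*
correlation 1/√2 is a different quantity and must not be placed in the
effect-correlation slot.  The implied chip covariance between score and
predictor is `h²·h²c/2` (0.192 for height), which the parent–offspring
trio simulator (`simulate_trios`) confirms; the test suite asserts all
four moments at 600,000 trios.

## The simulator

The simulator is the package's independent oracle, not a fixture.  Its
generative structure mirrors the mediation diagram behind the moment
model: non-null markers carry correlated effect pairs `(βᵢ, αᵢ)` (shared
null support; correlation `ρ`; total variances `R²GY` and `R²XY·R²GX`),
genotypes are independent standard Gaussians, and the non-genetic
residuals of `X` and `Y` are drawn jointly with covariance
`R²XY − ρ√(R²GY·R²XY·R²GX)` so the population moments of Table-level
parameters are reproduced exactly.  Combinations that would require a
residual correlation above 1 raise instead of renormalizing.  Per-marker
marginal estimation noise is drawn analytically (exact for independent
standardized markers), so a training replicate costs O(m); evaluation
cohorts generate genotypes in chunks and keep only the three projections.

Reduced-scale study conditions used by the tests: score-moment agreement
at m = 1,000, n = 2,000 (continuous) and n = 4,000 (binary) over 300
training replicates; full metric agreement on the coronary-disease preset
scaled to m = 2,000, n = 20,000 with 100 evaluation cohorts of 5,000
subjects.  Every analytic metric (AUC, categorical and continuous NRI,
IDI, capture, sensitivity/specificity) is asserted within 3 Monte Carlo
SEs of its counted counterpart.  What passing shows: the formulas are
correct expectations under the stated generative model.  What it does not
show: robustness to linkage disequilibrium, non-normal effect-size
distributions, binomial genotypes at extreme allele frequencies, or
heterogeneity between training and target populations — none of which
the moment model represents.

## Scenario presets and known inconsistencies

The three presets pin the study conditions: coronary disease (63,746
cases, 2.05 controls per case, m = 1e5, `R²GY = 0.3`, `π₀ = 0.8`,
`K = 0.15`, `R²XY = 0.052`, `R²GX = 0.3`), breast cancer (33,673 cases,
0.99 controls per case, `R²GY = 0.3`, `π₀ = 0.95`, `K = 0.05`,
`R²XY = 0.0375`), and height (continuous, m = 2.5e6, `R²GY = 0.48`,
`π₀ = 0.995`, family-history environment).  Prevalence and `π₀` variants
are constructor overrides, so the supplementary sensitivity tables are a
configuration change only.  `n` is the total training size; published
case counts convert through the stated controls-per-case ratio.

Recomputation reveals three internal inconsistencies in the published
reference tables, visible in the diff reports emitted by
`reproduce_tables` and deliberately **not** absorbed into this package:

1. The breast-cancer combined-score AUC column reproduces to printed
   precision only if the environmental variance is set to 0.052 (the
   coronary-disease value) instead of the stated 0.0375; the faithful
   values are ≈0.015 lower (e.g. 0.667 rather than 0.682 at genome-wide
   selection).  The published combined sensitivity/specificity pair
   (32%, 86%) shows the same signature; the faithful computation gives
   (28%, 87%).
2. The environmental AUC printed for the coronary-disease table (0.635)
   is the externally reported risk-score AUC; the model value at
   `R²XY = 0.052`, `K = 0.15` is 0.618.
3. Two isolated cells (a sign on one case-NRI entry, one infinite-sample
   case-NRI value) disagree with the otherwise-matching row and appear to
   be misprints.

## Numerical notes

Double precision throughout; no bespoke approximations of Φ beyond
scipy's.  Degenerate selection windows (no marker expected to pass) warn
and propagate a flagged zero-variance score, which the combiner resolves
to the environment-only fallback.  All simulation entry points take an
explicit integer seed; identical configurations reproduce bit for bit.
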