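# Methods

## The measurement problem

Six ordinal items record whether, when seeking medical advice or
treatment, each of the following is "not a problem" (0), "a small
problem" (1) or "a big problem" (2): knowing where to go, getting
permission, having the money to pay, distance to the health facility,
finding transport, and not wanting to go alone. In rural low-income
settings the first two are typically near-degenerate (almost everyone
answers "not a problem"), while the financial and geographic items vary
widely and share a common dimension. The package condenses the informative
items into a single factor-based score on the original 0–2 scale.

## Score building

**Adequacy gate.** Bartlett's sphericity statistic
−(n−1−(2p+5)/6)·ln det R with p(p−1)/2 df, and the Kaiser–Meyer–Olkin
measure Σr²/(Σr²+Σa²), where a are anti-image partial correlations from
R⁻¹. A warning (not an error) is raised when Bartlett is not rejected or
KMO falls below 0.5.

**Correlations.** Pearson on the 0/1/2 codes, listwise-complete — the
convention of the survey-software workflow this mirrors. A two-step
polychoric estimator (thresholds from the marginal cumulative proportions,
pairwise latent correlation by scalar ML over bivariate-normal rectangle
probabilities) is available for sensitivity analyses; it undoes the
categorization attenuation but is ~100× slower.

**Extraction.** Default is principal-component factoring (eigendecomposition
of R with its unit diagonal). Two reasons. First, the reported
eigenvalues are then the classical scree-plot/Kaiser eigenvalues, so the
"eigenvalue > 1.1" retention rule and the variance share
(`proportion_variance` = eigenvalue / number of items, i.e. share of
*total* item variance — the report labels this definition) carry their
textbook meaning. Second, on 0/1/2 codes the categorization attenuates
Pearson correlations enough that principal-axis loadings of a genuinely
loaded but skewed item (e.g. "going alone", ~88% zeros) fall below
conventional cutoffs even when its latent loading is 0.5; component-style
loadings remain interpretable against the 0.4 rule. Principal-axis
factoring with SMC communalities, optionally iterated (tolerance 1e-6,
max 100 iterations), is available via `extraction="pf"` / `iterate=True`.

**Stepwise descendant selection.** From the full set, every leave-one-out
analysis is evaluated; a removal is accepted when (a) overall KMO does not
drop by more than `kmo_tol` (default 0.01) and (b) the proportion of total
variance explained by the retained factors strictly increases. The best
accepted removal (largest variance share; ties broken by smallest
communality, then item order) is applied and the loop repeats, stopping
when no removal qualifies or two items remain. This composite rule is one
concrete reading of "removing an item does not significantly reduce the
quality of the factor analysis": the KMO guard vetoes removals of items
that carry common variance (dropping a loaded item typically costs
0.05–0.09 of KMO on calibrated data, far above the tolerance), while the
variance-share condition rewards shedding items that add denominators but
no common variance. Both knobs are exposed in `StepwiseConfig` so
alpha- or residual-based alternatives can be swapped in.

**Final cut.** On the surviving set, the number of dimensions is the count
of eigenvalues strictly above 1.1 (minimum one, with a warning), loadings
are varimax-rotated (Kaiser-normalized; single-factor solutions are only
sign-aligned so the largest-magnitude loading is positive), and items with
max |loading| > 0.4 define the score. Fewer than two survivors is an
error carrying the full trace.

**The score.** Arithmetic mean of the retained items, complete-case per
respondent (a missing retained item gives a missing score — this keeps
the score's k·score ∈ {0,…,2k} granularity and the interpretation of the
0 and 2 anchors). Summaries report mean, SD, median and IQR, unweighted
and weighted; quantiles interpolate linearly on midpoint-of-mass
positions (for four equally weighted values 0, 0.5, 1, 2 the median is
0.75), and the weighted SD uses the reliability-weights denominator
Σw − Σw²/Σw.

## Validity engine

Each variable is regressed on the score in a univariate model chosen by
type: linear (CE) via weighted least squares, logistic (OR) and Poisson
(IRR) via weighted GLMs, multinomial logistic (RRR, base category
"non-enrolled") via an in-package Newton fit because statsmodels'
multinomial does not accept weights. All variances are cluster-robust on
the household: CR0 sandwich scaled by G/(G−1)·(n−1)/(n−k), the scaling
used by the survey software this mirrors (with singleton clusters and
equal weights it reduces to HC1). Estimates for the exponentiated
families are exp(slope) with delta-method SE exp(b)·se(b); p-values are
two-sided Wald tests of the slope on the link scale.

Predictions at the anchor scores 0, 1, 2 are inverse-link transforms of
the fitted linear predictor; the 95% CI is formed on the link scale from
the clustered covariance and back-transformed, so probability bounds stay
in (0,1) and count bounds stay positive. The reported SE of a prediction
is the derivative of the inverse link times the SE of the linear
predictor. Out-of-range evaluation points warn but are computed.

CHE flags are share = OOP health spending / non-food spending with
inclusive thresholds at 40, 30 and 20%, nested by construction.

## Confirmatory stage

One-factor CFA by normal-theory ML on the sample covariance matrix of the
item codes (consistent with the Pearson default of the EFA; categorical
WLSMV estimation is out of scope). Identification fixes the factor
variance to 1, treating items symmetrically. Optimization is L-BFGS-B
with analytic gradients; residual variances are bounded below at 1e-6
times the item variance, and a solution at that bound is reported as a
Heywood case naming the item. Indices: χ² = (n−1)·F_ML with
df = p(p+1)/2 − 2p; RMSEA = sqrt(max(χ²−df,0)/(df(n−1))); CFI and TLI
against the diagonal (independence) model; SRMR over the standardized
residuals of the upper triangle including the diagonal. `compare_cfa`
flags per index which item set fits better (lower χ²/df, RMSEA, SRMR;
higher CFI, TLI).

## Synthetic surveys

The generator emulates the structural features the analysis relies on,
not any real joint distribution:

- **Design.** Three choice-based strata (voluntary insurance subscribers,
  subsidized cash-transfer recipients, non-enrolled) with default sample
  sizes 285/176/1326 (n = 1787). Households are filled per stratum with
  1 + Poisson(mean_household_adults − 1) adults (default mean 2,
  matching a design that interviews the subscriber and their partner).
  Population shares default to (0.05, 0.04, 0.91) — a plausible CBHI
  penetration for the setting; weights are population share / sample
  share, so weighted stratum totals reproduce the population shares
  exactly.
- **Items.** A graded-response-style model: unit-variance latent trait
  T = household effect + individual effect + Σβ·(standardized covariates),
  with var(household)/var(total random part) = `household_icc`
  (default 0.30); item j's latent response is λ_j·T + √(1−λ_j²)·noise cut
  at two thresholds. Default loadings (0.05, 0.05, 0.60, 0.60, 0.65,
  0.50) leave items 1–2 unloaded; default thresholds reproduce marginals
  typical of such surveys (98.3/98.6% "not a problem" on items 1–2;
  15/30/55% on money; 57/28/15% and 61/28/11% on distance and transport —
  the printed distance marginals exceed 100%, so the middle category
  absorbs the excess; 88/9/3% on going alone). With these defaults the
  expected score mean is ≈0.66 and the median/IQR land on 0.5 and
  (0.25, 1).
- **Covariates.** Simple parametric families (Bernoulli, Gaussian,
  log-normal, gamma), household-level where the variable is a household
  attribute; effect signs follow the construct-validity pattern (women,
  the poor, the chronically ill, remote households: higher barriers;
  educated, partnered, trusting, voluntarily insured: lower). OOP and
  non-food spending are independent of the trait, so CHE flags are null
  associations by construction.
- **Outcomes.** Drawn per respondent from logistic/Poisson models whose
  linear predictor is intercept + slope × (realized mean of items 3–6);
  default coefficients give, e.g., a 0.20 probability of forgoing a
  consultation at score 0 rising with OR 3.10 per point, and 3.69
  expected prenatal consultations at score 0 falling with IRR 0.87.
  Subset flags: recent illness 23.4% of adults; recent birth 21.5% of
  women (≈ 418 and ≈ 200 respondents at the default n).

**What passing tests do not show.** The generator draws items from an
exact one-factor latent model, so a full-set CFA also fits in absolute
terms; only the standardized residuals (SRMR) systematically favor the
reduced set. Real data, where the weak items misfit the common factor,
can degrade the full model much more visibly. Likewise Cronbach's alpha
on the calibrated synthetic items (~0.5) is lower than on real items whose
observed correlations are stronger; alpha here is a computed output, not
a calibration target. Reporting heterogeneity, informative missingness,
and any supply-side structure are not modeled.

## Problem sizes and numerical choices

Monte-Carlo checks in the test suite use the default study-scale design
(n = 1787): 100 seeds for structure recovery, 200 replicates for
confidence-interval coverage of a known odds ratio, 1000 replicates for
the null rejection rate — sizes at which binomial noise is well inside the
asserted bands. Correlation matrices are symmetrized and clipped to
[−1, 1] before validation; communality iteration stops at 1e-6; the
varimax SVD iteration stops at a 1e-12 relative criterion gain; the
near-singular correlation case (items correlated ≈ 1) raises from the KMO
inversion with advice to drop an item. Multinomial Newton iterations stop
at a 1e-10 step norm with a 100-iteration cap. Determinism: every random
draw flows from one numpy Generator seeded by the config; two runs with
equal configs are byte-identical.

## Known limitations

- Polychoric correlations are pairwise-ML only (no full-information fit)
  and are not propagated to the CFA stage.
- The multinomial fit supports a single predictor plus intercept — all
  this pipeline needs — not arbitrary design matrices.
- No oblique rotations, ML/WLS factor extraction, or multi-group models.
- Weighted quantiles use one (documented) convention; software differs
  here and IQR endpoints on coarse score supports are convention-sensitive.
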