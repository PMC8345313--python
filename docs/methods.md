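# Methods

`svdburden` implements a latent-variable analysis of total MRI-visible
cerebral small vessel disease (SVD) burden and cognition, together with a
calibrated synthetic cohort generator so the whole pipeline can be run and
validated without access to restricted cohort data. This note documents the
statistical models, the generator, the numerical choices, and the known
limitations.

## The measurement models

Total SVD burden is modelled as a single latent variable measured by four
MRI markers: white matter hyperintensity volume normalized by intracranial
volume (WMH/TIV, continuous), a computational count of visible perivascular
spaces (PVS, continuous), and the presence of lacunes and of cerebral
microbleeds (binary). Binary and ordinal indicators are treated as probit
discretizations of standard-normal latent responses: a threshold
τ = Φ⁻¹(1 − prevalence) cuts the continuum, and loadings of categorical
indicators are standardized probit coefficients on the latent-response
scale. A parallel "visual-rating" SVD latent uses the ordinal deep and
periventricular Fazekas scores (0–3), the basal-ganglia PVS rating (0–4)
and the same two binary markers — the reconstruction used in earlier
sum-score approaches to SVD burden.

Cognition follows a bifactor structure: ten tests load on a general factor
g, and each test additionally loads on one of three domain factors
(processing speed, verbal memory, visuospatial ability) orthogonal to g and
to each other. Single-factor models per domain (and for g, using all ten
tests) serve the outcome-by-outcome regressions; the full bifactor model
partitions the SVD association into general and domain-specific paths.

## Estimation: mixed correlations + DWLS

Fitting is two-stage, the conventional approach for categorical SEM:

1. **Pairwise latent correlations.** Pearson for continuous pairs,
   polyserial for continuous–categorical, polychoric for
   categorical–categorical, each on pairwise-complete observations with
   thresholds fixed at the univariate margins and the correlation maximizing
   the bivariate-normal likelihood. Bivariate normal rectangle
   probabilities use the exact Owen's-T identity (`scipy.special.owens_t`),
   accurate to ~1e-14, well inside the 1e-10 requirement. Optimization is
   bounded scalar minimization with a 1e-10 ridge on ρ² that breaks ties on
   flat likelihoods toward lower |ρ|. Estimates at the boundary are clamped
   to |ρ| = 1 − 1e-6 and flagged (detection threshold 1e-4, wider than the
   clamp, because bounded optimizers stop strictly inside the bracket).

2. **Diagonally weighted least squares.** The model-implied correlation
   matrix σ(θ) comes from standard linear structural algebra
   Σ = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ in correlation metric (delta parameterization:
   every indicator's implied variance is 1 and residual variances are the
   unit complement of the explained variance, not free parameters). The
   discrepancy F(θ) = Σ (s−σ(θ))²/w uses per-moment asymptotic variances as
   weights: (1−r²)²/n for Pearson pairs, observed-information variances for
   polyserial/polychoric pairs. Minimization is trust-region nonlinear
   least squares with finite-difference Jacobians; convergence is declared
   at a Newton decrement below 1e-6 relative to (1 + F), a scale-invariant
   version of a gradient-norm criterion (the raw gradient norm depends on
   the weight scale); up to five deterministically jittered restarts on
   failure. Observed covariates ride along as single-indicator latents with
   unit loading, free to correlate with each other and with exogenous
   latents, and regressed onto the cognitive factors.

**Robust statistics.** The full asymptotic covariance Γ of the stacked
pairwise estimates is computed from per-observation influence functions of
the two-stage estimators (score of ρ plus plug-in corrections for
estimated thresholds and for the mean/SD of the continuous margin), with
derivative matrices obtained by central differences at the estimates.
Standard errors are sandwich-type, (JᵀWJ)⁻¹JᵀWΓWJ(JᵀWJ)⁻¹. The test
statistic is mean-and-variance adjusted in the Satterthwaite style: with
U = W − WJ(JᵀWJ)⁻¹JᵀW, the adjusted statistic is F̂·tr(UΓ)/tr((UΓ)²) on
df\* = tr(UΓ)²/tr((UΓ)²) degrees of freedom, so its first two moments match
a chi-square under correct specification. The package validates this by
simulation (500 replications of a binary-indicator model at n = 540: mean
statistic within 3% of mean df\*) rather than by matching any particular
software implementation bit for bit.

**Identification.** Default rule: factor variances (and endogenous
disturbance variances) fixed to 1 with all loadings free; the alternative
first-loading-fixed rule is available, and standardized solutions are
invariant to the choice (tested). Factors are sign-normalized so each
factor's first indicator loads positively. Heywood directions (explained
variance above 1) floor the residual at zero and flag the indicator rather
than aborting; a factor whose standardized loadings all fall below 0.1 is
flagged as vacuous. Globally non-identified structures (e.g. a bifactor
whose general loadings are truly zero) can still converge to a locally
identified equivalent optimum; such cases surface through severalfold
inflated path standard errors rather than a hard flag.

## Fit assessment

RMSEA, CFI, TLI and SRMR are computed from the adjusted chi-square and its
adjusted df, with the zero-correlation independence model as baseline.
RMSEA uses the (n−1) denominator by default (configurable to n; software
conventions differ). TLI is deliberately unclamped and can exceed 1; CFI
is clamped to [0, 1]. SRMR is the root mean square of the residual
correlations; thresholds are estimated saturated in stage one, so they add
nothing to SRMR. Acceptability verdicts use RMSEA < 0.06, CFI > 0.95,
TLI > 0.95, SRMR < 0.08. n for RMSEA is the median pairwise-complete count.

## Auxiliary inference

- **Williams test** for two dependent correlations sharing a variable:
  t = (r12−r13)·√[(n−1)(1+r23) / (2|R|(n−1)/(n−3) + r̄²(1−r23)³)] on n−3 df,
  with |R| the determinant of the 3×3 correlation matrix and r̄ the mean of
  the compared correlations. One-sided p in the direction of the observed
  difference; both sides stored. In the pipeline the test compares
  factor-score-based predictor–outcome correlations (the observable-proxy
  convention; a model-implied variant would be the natural alternative but
  the published analysis does not specify how latent-effect uncertainty
  entered, and factor scores are the default here).
- **FDR**: Benjamini–Hochberg step-up adjustment (via
  `statsmodels.stats.multitest`), one family per results grid (24 rows per
  predictor) plus one family for the four bifactor paths; a global family
  is configurable because the published family structure is not recoverable
  from the printed values.
- **Residualization**: manifest cognitive scores are residualized on the
  scan–test interval (days) by simple linear regression on complete pairs
  before any latent modelling; missing cells stay missing; a constant
  interval column degenerates to mean-centering.

## The synthetic cohort generator

All manifest variables derive from one multivariate-normal latent layer:
exogenous latents (SVD burden, vascular risk, and the observed-covariate
continua for age, sex, depression score and age-11 IQ) with a documented
correlation matrix, and endogenous cognitive factors defined by
standardized structural paths with mutually orthogonal disturbances scaled
to unit total variance. Indicators are loading·latent + scaled residual;
continuous columns are affinely rescaled to target means and SDs, binary
and ordinal columns are probit-thresholded. The scan–test interval effect
is added to the manifest cognitive scores last, followed by
missing-completely-at-random deletion (default 1% per cognitive column).
Generation is deterministic given (parameters, n, seed), and the implied
population correlation matrix equals the SEM engine's σ(θ) at the
generating parameters (tested to machine precision).

Calibrated defaults:

- SVD marker loadings are the square roots of the published communalities
  (25/10/32/18%); lacunes and microbleed prevalences 5.1% and 12.0%;
  continuous marginals from the published cohort table (PVS 258.7 ± 94.6,
  WMH/TIV 0.008 ± 0.009, and so on).
- Structural paths default to the published bifactor estimates (SVD→g
  −0.224, →speed −0.325, →memory −0.133, →visuospatial 0.075) plus modest
  documented covariate effects (age-11 IQ→g 0.5 dominating, age ≈ 0 at this
  narrow age range of SD 0.7 years, vascular-risk↔SVD correlation 0.2).
- Cognitive g loadings lie in 0.5–0.75 and domain loadings in 0.3–0.6, with
  deliberately heterogeneous g/domain ratios across the tests of each
  domain. This heterogeneity is what identifies the bifactor split of the
  SVD association; with near-proportional profiles the split is almost
  unidentified and its standard errors are several times the published
  ones. At these defaults the implied bifactor path SEs at n = 540
  (0.07/0.09/0.10/0.13 for g/speed/memory/visuospatial) match the published
  magnitudes. The visuospatial tests lean most on g, reproducing the
  near-degenerate independent visuospatial factor.
- Visual-rating loadings on the SVD continuum default to 0.32/0.32/0.24.
  These are *effective* loadings absorbing both rater noise and the
  construct gap between coarse visual scales and computational measures;
  they are set low so that the ratings-based latent is the weaker proxy for
  cognition-relevant SVD burden, the ordering the published comparison
  found. Fazekas-style thresholds put most mass in categories 0–1, as in
  community-dwelling cohorts of this age.
- WMH/TIV and PVS are generated with normal marginals. The real WMH
  distribution is right-skewed, but the analysis operates on correlations,
  so the marginal shape is largely immaterial; the skewness is anyway not
  recoverable from published summary statistics.

What the generator does **not** emulate: non-normal (skewed, zero-inflated)
marker distributions; informative missingness; construct differences
between the visual-rating and computational SVD latents beyond a loading
discount; site/scanner effects; and any spatial or image-level structure.
Passing recovery tests therefore demonstrates the correctness of the
estimators under the assumed probit-normal world, not robustness to the
messiness of real imaging data.

## Problem sizes and experiment design

Recovery experiments simulate n = 100,000 so that Monte-Carlo noise is
small against the published point estimates; study-scale behavior
(power, false-positive patterns, chi-square calibration) is examined at
n = 540 with seeded replications (500 for the chi-square mean property; 50
for the qualitative bifactor pattern). The exhaustive tetrachoric oracle
sweep covers every 2×2 table with all cells ≥ 5 up to n = 40 plus a seeded
random sample up to n = 200; the oracle integrates the bivariate normal
density over ρ (Plackett identity) and shares no code with the estimator.

At n = 540 the qualitative bifactor pattern (all four separate regressions
significant; bifactor significant for g and speed only, under a truth with
only shared and speed-specific effects) reproduces in roughly 86% of
replications. The shortfall from a higher rate is a property of the
method at this sample size: ridge curvature between the general and domain
paths biases the null domain estimates slightly upward, elevating their
false-positive rates, and speed power is ~92–96%.

## Known limitations

- Diagonal-weight DWLS only; the full-weight WLS variant is out of scope.
- Pairwise-present moments assume missingness ignorable for correlations;
  no FIML.
- Factor scores replace categorical indicators by truncated-normal
  conditional means; the closed-form reliability
  √(λᵀΣ⁻¹λ) is exact only for continuous indicators.
- The Williams comparison uses factor-score correlations, which attenuates
  latent effects; it is a comparison of observable proxies, not of the
  latent regressions themselves.
- Wald-type confidence intervals (estimate ± 1.96·SE) throughout; no
  profile or bootstrap intervals.
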