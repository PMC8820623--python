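# Methods

`agridiet` implements an analysis pipeline linking farm production
diversity, market access and women's dietary diversity in a smallholder
farming population, together with a calibrated synthetic survey generator
that stands in for the original (undeposited) field data. This note
records the models, the conventions, and the design choices that were
genuinely open.

## Dietary diversity

Each woman contributes four 24-hour recalls, one per season. Food intakes
are classified into the 10 MDD-W food groups (grains/roots/tubers, pulses,
nuts and seeds, dairy, meat/poultry/fish, eggs, dark green leafy
vegetables, vitamin-A-rich fruits and vegetables, other vegetables, other
fruits). The seasonal WDDS-10 is the count of groups consumed; no minimum
quantity threshold applies, and olive oil never counts because it carries
no qualifying micronutrients (it is tracked separately because so many
study farms produce it). The annual WDDS-10 is the arithmetic mean of the
four seasonal scores — exactly, by construction — and the MDD-W flag is
`annual >= 5`. The flag is defined on the annual score (a per-season flag
is derivable from the seasonal scores but is not the headline). Women with
missing seasons are rejected rather than imputed, mirroring the survey's
exclusion rule.

The per-group annual consumption score is (consuming recalls)/4, taking
values {0, 0.25, 0.5, 0.75, 1}.

Seasonal comparisons use a generalized Cochran–Mantel–Haenszel test of
season × consumption association with women as strata (each stratum is a
2×4 table with one observation per season). Women who consume a group in
all four seasons or in none carry no information; they are dropped and
counted. For this design the statistic coincides exactly with Cochran's Q,
which the test suite uses as an independent cross-check. Pairwise seasonal
WDDS contrasts use the paired Wilcoxon signed-rank test (robust on bounded
integer scores). The producing-vs-not comparison of consumption scores is
between *independent* groups of women, so the headline p-value is the
rank-sum (Mann–Whitney) test even though survey write-ups sometimes label
this contrast a signed-rank test.

## Production diversity

Five indices per farm, all computed from the product portfolio and its
annual monetary values:

* **PDI** — count of distinct products out of the 29-product reference
  catalogue (0/1 coding: a token 1-USD product counts fully).
* **SDI** — Simpson index `1 − Σ s_i²` over monetary value shares of
  products; invariant to currency rescaling.
* **GPDI** — count of distinct scorable MDD-W groups (0–10). Products
  without an MDD-W group (olive oil, table olive, garlic, honey, hot
  pepper) are excluded.
* **GSDI** — Simpson index over value shares of the 10 groups, with
  unclassified value removed from numerator and denominator. A farm with
  production only in unclassified products has no defined group shares;
  the strict function raises, while population-level scoring assigns 0
  (maximal concentration) so that full-sample regressions are defined.
  `GPDI ≤ PDI` always; no order between GSDI and SDI is implied (removing
  the unclassified value can move the group index either way).
* **NFD** — Nutritional Functional Diversity. A 29×18 product-nutrient
  matrix is divided column-wise by WHO recommended intakes for adult
  women, z-scored across products (ddof = 1), converted to a Euclidean
  product–product distance matrix and clustered hierarchically. The
  dendrogram is read ultrametrically: leaves at height 0, an internal node
  at half its cophenetic merge distance, branch length = parent height −
  child height. A farm's NFD is 100 × (branch length of the subtree
  linking its products) / (total branch length).

Open choices and how they were fixed:

* **Linkage.** The clustering method behind the reference analysis is not
  recorded; the default is average linkage (UPGMA), with single, complete
  and Ward available. All four are monotone, so the ultrametric reading is
  safe; non-monotone heights raise.
* **Root convention.** By default the farm subtree includes the path to
  the root. This makes a monoculture score > 0 and makes NFD monotone
  under product addition (the properties the acceptance suite asserts);
  the exclusive convention (minimal spanning subtree between the farm's
  leaves only) is available via `include_root_path=False`.
* **Nutrient fixture.** The national food-composition values are not
  public. The bundled matrix (`nutrients_synthetic.csv`) is synthetic:
  plausible per-portion magnitudes with correct group structure
  (dairy high in calcium, meats in B12/zinc, leafy greens in vitamin A
  and folate, ...), jittered product-by-product. NFD values computed from
  it are therefore structurally sensible but not nutritionally authoritative.
  The source listing names 17 nutrients while stating 18 columns; the 18th
  column is filled as vitamin B6 and documented as an ambiguity. Sodium is
  standardized like every other column.

Farm orientation uses the 80% rule on value shares: > 80% of production
value kept for own consumption → SELF_CONSUMPTION; > 80% sold →
MARKET_ORIENTED; otherwise MIXED. Annual WDDS-10 across the three classes
is compared with a Kruskal–Wallis rank test.

## Market access

A market's MDI is the Shannon entropy `−Σ P_i ln P_i` (nats) of its
species-sale proportions. A household's HAMDI is the mean MDI of the two
markets nearest to its home "as the crow flies" (exclusive-frequentation
hypothesis; k = 2 is the default and configurable), together with the
distance to the nearest market. Crow-flies distances are great-circle
(haversine) kilometres; at a ~100 km governorate scale this differs from
planar distance by far less than any quantity of interest. Selection ties
at the cut-off rank are broken by market id so results are independent of
input order. Whether real-market proportions are vendor-weighted or
presence-weighted is unknowable from the available description; the
pipeline consumes proportion vectors directly and is agnostic.

## Econometric model

The structural equation regresses annual WDDS-10 on one production
diversity index (endogenous) plus woman covariates (age, three education
dummies vs no schooling, domestic work-time, expenditure responsibility,
non-farm income, off-farm agricultural income, on-farm participation),
household covariates (head age, household size, wealth score) and market
covariates (HAMDI, nearest-market distance). The wealth score is the
first principal component of standardized binary asset indicators,
affinely rescaled to [0, 100]; constant indicators are dropped with a
warning, and the sign is fixed so more assets score higher.

Production diversity is instrumented by three agro-climatic zone dummies
(reference: the modal upper-arid-temperate zone) and farm seniority — four
excluded instruments, three overidentifying restrictions.

**LIML.** With `W = [y, endogenous]`, `M_X` annihilating the included
exogenous block and `M_Z` annihilating the full instrument set, κ is the
smallest root of `det(W′M_X W − κ W′M_Z W) = 0`; the coefficient vector is
the k-class estimator at k = κ. κ ≥ 1 always, with κ = 1 exactly in a
just-identified model, where LIML, 2SLS and ratio-form IV coincide (the
suite asserts agreement to 1e-8 and checks an over-identified n = 40 fit
against an independently coded eigen-solve + k-class oracle). Standard
errors are the heteroskedasticity-robust sandwich with HC1 small-sample
scaling, built from `(I − κM_Z)R`. Standardized slopes are
`β̂₁ · sd(x)/sd(y)`.

**Diagnostics.**

* *Underidentification*: Anderson canonical-correlation LM statistic,
  `n·(smallest canonical correlation)²`, χ² with `L − m + 1` degrees of
  freedom (no clustering, so the Kleibergen–Paap variant is out of scope).
* *Weak instruments*: Cragg–Donald minimum-eigenvalue F (with one
  endogenous regressor this is the first-stage F on the excluded
  instruments after partialling the included block), reported against the
  Stock–Yogo critical values embedded as data (transcribed from the
  published tables; one endogenous regressor, TSLS and LIML size criteria
  at 10/15/20/25%, TSLS bias criteria). Untabulated cells report "not
  tabulated" rather than an interpolation. The default reference is
  LIML / 10% maximal size.
* *Overidentification*: the Sargan statistic (n·R² of IV residuals on the
  instrument set) and the robust Hansen J as the headline. J is the
  minimized two-step GMM criterion with the first-step weight built from
  the LIML residuals; evaluating the quadratic form at a non-minimizing
  point is oversized in finite samples, while this implementation rejects
  at 4–6% under a nominal 5% test at n = 300. The weight matrix is
  inverted by pseudo-inverse to tolerate near-singularity at small n.

Covariates that are constant in a given (small) sample are dropped with a
logged warning before estimation; genuine collinearity raises an error
naming the offending columns. Significance is starred at 10/5/1%.

## Synthetic survey generator

The generator emulates a cross-sectional two-stage farm/diet survey of 290
households (one woman aged 20–49 per household, four quarterly recalls, 24
weekly markets across four agro-climatic zones). Its purpose is to provide
data with *known ground truth* for estimator validation, with default
moments matching the published study population. All randomness flows from
a single seed through per-stage substreams (markets, farms, households,
women, diet), so a config + seed pair reproduces the dataset byte for byte.

Generation proceeds in stages:

1. **Zones and seniority.** Zone from (0.15, 0.55, 0.20, 0.10); seniority
   log-normal with median 25 y and log-SD 0.55.
2. **Confounder.** A latent household factor `u ~ N(0,1)` loading on both
   production diversity (0.35) and diet (0.25) — the endogeneity the IV
   machinery must undo.
3. **Production portfolio.** Each farm has a diversity propensity
   η = centred zone effect + 0.78·ln(seniority/25) + 0.35·u + noise(0.30).
   Each food group (and each unclassified product) is produced with
   probability `expit(α_g + η)`. The intercepts α_g are solved
   deterministically (Gauss–Hermite quadrature over the zone-mixture
   distribution of η, plus a fixed-point correction for the redrawing of
   empty portfolios) so that the population prevalence of each group
   equals its survey target exactly — e.g. 81.4% meat producers, 53.5%
   olive oil, 19.7% dairy. Produced groups draw a first product by
   within-group weights (sheep dominate meat; wheat dominates grains) and
   extra same-group products at a propensity-shifted base rate of 0.15.
   This yields median PDI 3 with IQR 2–4. A count-first scheme (draw PDI,
   then fill products) was rejected because conditioning product identity
   on a drawn count cannot match per-group prevalences exactly.
   Total production value is log-normal (median 1,960 USD, log-SD 1.39)
   with an ln-value slope of 0.5 on PDI − 3 (reproducing the observed
   diversity–value correlation ~0.5); value splits across products are
   Dirichlet(0.45). The farm-level self-consumption share is a U-shaped
   two-component Beta mixture (most farms sell nearly everything; a
   substantial minority keeps nearly everything).
4. **Households.** Size = 1 + Poisson(4.31) (mean exactly 5.31; the SD,
   2.08, is moderately above the survey's 1.81 — an accepted simplification
   since only the mean is a calibration moment). Head age N(44.6, 12.3);
   eight binary asset indicators loaded on a latent wealth factor that also
   enters the diet equation (the estimated models use the PCA wealth score,
   a noisy proxy of the latent factor — harmless for the production-diversity
   slope because wealth is independent of the instruments and confounder).
5. **Women.** Age N(35, 7.9) clipped to 20–49.9; education multinomial
   (23.1/34.8/31.0/11.1%); domestic hours log-normal (median 25.3);
   activity/income flags at survey prevalences; BMI as a descriptive field.
6. **Diet (LINEAR mode, default).** A latent annual score
   `y* = 5.989 + 0.10·PDI + covariate effects + 0.25·u + N(0, 0.85)`,
   with covariate effects matching the fitted magnitudes of the reference
   analysis (education +0.33/+0.53/+0.96, household size +0.104, wealth,
   ages, work variables). `4·y*` is stochastically rounded (unbiased) to
   an integer total, which is split into four seasonal integer scores by a
   sum-preserving largest-remainder allocation tilted by season offsets
   (spring +0.17, winter +0.06, autumn −0.10, summer −0.13 — reproducing
   the observed spring peak) plus within-woman seasonal noise (SD 0.95).
   The annual WDDS-10 recomputed downstream therefore equals the mean of
   the seasonal scores exactly. Each seasonal score is decomposed into a
   concrete group set by weighted sampling without replacement (grains
   near-universal, nuts/eggs rare), with a woman-level persistent taste
   (correlation parameter 0.3 across seasons — the within-woman recall
   correlation is not reported in the study, so it is exposed as a
   parameter rather than asserted) and a ×4 dairy weight when the farm
   produces dairy (reproducing the producing-vs-not dairy contrast).
   `BERNOULLI_GROUPS` mode instead draws per-group per-season logistic
   indicators (spring-elevated, dairy bonus) and lets WDDS emerge.
7. **Markets and space.** Households and 24 markets are uniform on a
   111.3 km square (calibrated once so the median household-to-nearest-
   market distance is 11.04 km), mapped to GPS around (35.0°N, 9.4°E).
   Each market's species-proportion vector is constructed to carry an
   exact Shannon entropy drawn from N(1.48, 0.08) (a one-dominant-species
   family solved for the target entropy, then permuted), so the median
   HAMDI matches the survey's 1.48 with a realistically narrow spread.

**Calibration policy.** Defaults were calibrated once against the
published moments and the designed endogeneity contrast, then frozen:
pooled over independent seeds, mean annual WDDS-10 = 6.53, spring mean =
6.70, mean household size = 5.31, median seniority = 25, median
nearest-market distance = 11.04 km, meat prevalence = 81.4%, median
HAMDI = 1.48, each within two Monte-Carlo standard errors over 20 seeds;
and with instrument strength set so the median Cragg–Donald F (~19.5)
matches the reported PDI first stage, the median adjusted-OLS slope
overshoots the structural β₁ = 0.10 by ≥ 25% while the median LIML slope
stays within ±10% (medians, not means: LIML has no finite moments under
weak identification).

**What the generator does not emulate.** Sampling weights and cluster
design; spatial autocorrelation beyond zone effects; price series and
seasonal production dynamics; multi-woman households; recall measurement
error. Passing tests demonstrate internal consistency of the pipeline and
estimator behaviour under a realistic survey-shaped data-generating
process — not conclusions about any real population.

## Numerical conventions

* Projections via least squares (no explicit projection matrices);
  generalized eigenvalues via `scipy.linalg.eigvals`; κ clipped to ≥ 1
  with failures below 1 − 1e-8 raised as errors.
* Column standardization uses ddof = 1 throughout.
* Dendrogram ties are resolved by SciPy's deterministic linkage ordering;
  the total branch length is invariant to the pairing of equidistant
  merges.
* CSV output uses pandas' default float repr, which round-trips float64
  exactly; determinism tests compare bytes.
* Monte-Carlo problem sizes in the test suite: 1000 replicates (n = 300)
  for the Hansen J size check, 500 for LM uniformity, 200 survey
  replicates (n = 290) for recovery, 20 seeds for population calibration.

## Known limitations

* The nutrient fixture is synthetic; NFD levels (e.g. the ~19 median on
  default populations) depend on it and should not be read as the study's
  NFD scale, even though the score's structural properties (0–100 range,
  monotonicity, value-invariance) hold regardless.
* Stock–Yogo values cover one endogenous regressor with up to 10 excluded
  instruments; other cells report "not tabulated".
* The Hansen J headline uses a two-step GMM criterion with LIML first-step
  residuals; under strong heteroskedasticity at very small n (< ~50 with
  many instruments) the pseudo-inverse guard can make the test
  conservative.
* `seasonal_tests` drops degenerate strata silently into a count column;
  with very small samples whole groups can be degenerate, returning a null
  statistic rather than an error.
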