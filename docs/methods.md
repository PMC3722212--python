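# Methods

`conflictpci` analyses geographically stratified attitude surveys about
illegal hunting (poaching) of large carnivores — brown bear, wolf, wolverine
and lynx — across Norway and Sweden. Because the original telephone-survey
microdata are not public, the package pairs every analysis stage with a
synthetic-data generator that encodes the study's design and its published
effect structure, so that each estimator can be validated by parameter
recovery.

## The survey design being emulated

One stratum per municipality: 429 Norwegian municipalities (18 counties) and
280 Swedish municipalities (19 counties), 4–5 completed interviews each
(~3,200 respondents in total). Sixteen 5-point Likert items
("strongly disagree" … "strongly agree"); items 6–9 state that poaching of
bear, wolf, wolverine and lynx, respectively, is acceptable. Demographics:
sex, age, education (four ordered levels). Region covariates: human density,
a big-game-hunting-tradition flag, sheep density and a wolf-zone flag
(Norway only — Sweden has no wolf zone and its sheep are fenced), and
county-level current and historical carnivore densities per species.

## Response model of the generator

Respondent `r` in municipality `m` has acceptance propensity

    eta_r = b0 + b_country·I(Norway) + b_age·age + b_sex·I(female)
            + b_edu(level) + u_m,        u_m ~ N(0, sigma_u²).

Each species item is thresholded from the latent score `L_rs = eta_r + q_rs`
where `q_rs = logit(Phi(Z_rs))` and the `Z_rs` are standard normal with
common correlation `rho` (a shared respondent factor plus species-specific
noise). Since `Z_rs` is standard normal, `q_rs` is *exactly* standard
logistic, so with the third cut point fixed at 0,

    P(item_s >= 4 | covariates, u_m) = expit(eta_r)

holds exactly: the binarized items follow the binomial random-intercept
GLMM whose coefficients are the generator's inputs, while the full 5-category
distribution (needed by the conflict index) and the inter-species
correlation remain controllable. The remaining 12 items come from an
equicorrelated Gaussian battery sharing the respondent factor, thresholded
at standard-normal cuts, which makes the battery's Cronbach's alpha tunable
through one equicorrelation parameter.

Key defaults (all configurable):

| parameter | default | why |
|---|---|---|
| country gap `b_country` | 1.35 log-odds, Norway high | published respondent-model estimate; the source table prints the nonzero coefficient against a zero Norway row while its text says Norwegians accept ~4× more — the package treats 1.35 as the magnitude of the Norway−Sweden gap with Norway the high-acceptance country |
| age, sex, education effects | 0.016/yr; −0.18 female; 0 / 0.41 / 0.79 / 1.36 | published estimates (reference: male, secondary school) |
| intercept `b0` | −4.98 | calibrated in closed form so the marginal binarized rates land at ~3.5% (Sweden) and ~13% (Norway): for small p, E[expit(eta)] ≈ exp(mean eta)·exp(var(eta)/2) with var(eta) ≈ 0.59 from the covariate and random-intercept spread |
| municipality SD `sigma_u` | 0.5 | moderate between-municipality heterogeneity on the log-odds scale |
| species-latent correlation `rho` | 0.90 | calibrated so the mean pairwise Spearman correlation of items 6–9 falls in the observed 0.77–0.91 band (it lands near 0.84) |
| big-game tradition | P = 0.63 (NO), 0.23 (SE) | reported shares of respondents in strong-tradition municipalities |
| carnivore cross-species copula correlation | 0.765 = 2·sin(π·0.75/6) | the Gaussian-copula value whose lognormal Spearman correlation is 0.75, the reported bear–wolverine collinearity |
| demographics | age ~ U(18, 80); sex Bernoulli(0.5); uniform education | neutral defaults; the real marginals were not published |

Seeding: one master seed; stages (regions, demographics, responses) draw
from `SeedSequence(seed, spawn_key=(stage,))` streams, so outputs are
byte-identical given config + seed.

What the generator does **not** emulate: real geography (counties are
contiguous index blocks, the wolf zone is a deterministic block of
municipalities), response-rate thinning (completed interviews are emitted
directly), county-level attitude heterogeneity beyond what municipality
intercepts aggregate to, item non-response (off by default), and the real
registry covariates — densities are synthetic lognormals. Passing tests
therefore demonstrate that the *estimators* are correct and calibrated
under the design's sampling structure, not that the synthetic data
reproduce every feature of the real survey.

## Potential Conflict Index

Scores are the Likert codes centered to −2…+2 (neutral = 0). For a group of
n scores with extreme m:

* **PCI₂** (default): `D / delta`, where `D` sums `|x_i − x_j|` over all
  unordered pairs with strictly opposite signs (neutrals pair with nothing
  but count in n) and `delta = floor(n/2)·ceil(n/2)·2m` is the
  half-at-each-extreme total — the standard maximal-split normalization,
  which also settles odd n.
* **PCI₁**: `2·min(X_a, X_u)/(n·m)` with `X_a`, `X_u` the summed magnitudes
  of the agreeing and disagreeing sides.

The source description mixes the two generations (its printed formula is
typographically broken and its verbal description matches the
first-generation index while naming the second), so both are implemented
behind one flag, defaulting to PCI₂. An exhaustive brute-force enumeration
over every score multiset with n ≤ 6 pins the implementation; bounds, sign
symmetry and minority-extreme monotonicity hold on every enumerated input.
All-neutral groups return 0 with a logged note; groups with n < 2 are
undefined; municipality-level groups (n = 4–5) are computed but flagged
`small_group` (n < 8) because tiny groups cannot pin down a divergence
index. Group-level confidence intervals use a seeded percentile bootstrap
over respondents (B ≥ 100); the published tables state no interval method,
so this is the package's choice, as is the across-county t-interval used in
the PCI summary table and the Wilson score interval used for binarized
acceptance percentages.

## Correlations and reliability

Spearman correlations use midranks for ties; the attached standard error is
`SE_r = sqrt((1 − r²)/(n − 2))`, the convention that reproduces the
published tables' SEs at both county (r = 0.84, n = 18 → 0.14; r = 0.80,
n = 19 → 0.15) and individual sample sizes; p-values use the matching
t-approximation. Cronbach's alpha ships in raw (default) and standardized
variants with listwise deletion of incomplete rows (logged). The
multicollinearity screen flags predictor pairs with |r_sp| > 0.7 by default,
the level at which co-occurring carnivore densities (~0.75) were treated as
too collinear to enter one model.

## Mixed models

The respondent-level acceptance model is a binomial-logit GLMM with a
municipality random intercept, fitted by maximum likelihood with the random
effect integrated out by 25-node Gauss–Hermite quadrature (plain, not
adaptive: with cluster sizes of 4–5 and sigma_u ≈ 0.5 the quadrature error
is negligible, verified against `lme4::glmer(nAGQ = 25)` to 0.02 on the
coefficients). Optimization is bounded L-BFGS-B over (beta, sigma ≥ 0) with
an analytic gradient, started from the ordinary GLM fit; SEs come from the
numerically differentiated observed information. |beta| > 15 triggers a
separation warning. This fitter is hand-written because no installed Python
library provides ML binomial GLMMs with log-likelihoods comparable across
fits — which the elimination procedure needs. County-level Gaussian models
(mean acceptance or PCI per county × species, county random intercept)
delegate to statsmodels `MixedLM` with `reml=False` for the same
comparability; if the variance estimate collapses the fit falls back to OLS,
whose profile ML log-likelihood is the sigma_u = 0 limit.

Model terms are declarative (numeric, categorical block with a configurable
reference level — shipped defaults: male, secondary school, Norway — or
quadratic block). The quadratic option exists for log-transformed human
density, encoding the hypothesis that conflict peaks at intermediate
(mixed rural–urban) densities; a simulated peak recovers a negative
second-order coefficient. Nested models are compared by likelihood-ratio
tests (chi² = 2·Δloglik clipped at 0; df = difference in fixed-effect
columns, the variance parameter being common). Backward elimination
repeatedly drops the single non-forced term with the largest LRT p among
those above the 0.05 threshold (ties broken by term name; categorical and
quadratic terms move as blocks) and refits until all retained non-forced
terms are significant; sex, age and education are forced by default in the
respondent model. Null-covariate LRT p-values are approximately uniform
(KS-checked at 500 replicates), and with carnivore-density covariates
generated null, elimination removes them at near the nominal rate while
always retaining the generated country effect. Odds ratios are
`exp(beta)` with Wald 95% limits; `exp(1.435 ± 1.96·0.158)` reproduces the
published "4.2 (3.10, 5.76)", which is consistent with a country estimate
of ~1.43 rather than the rounded 1.35 printed beside it — a source-internal
tension the package reproduces but cannot resolve.

## Parameter recovery and problem sizes

The recovery experiment regenerates the full design (709 municipalities,
4–5 respondents, sigma_u = 0.5, all fixed effects at the shipped defaults)
and refits the GLMM on the binarized bear item; a single item per respondent
keeps the fitted likelihood exactly the generating one (stacking all four
species rows, as the analysis pipeline does for its model table, adds
respondent-level dependence the municipality intercept does not model — a
documented limitation inherited from the emulated analysis, which likewise
used no respondent random effect). Over replicates the country and
graduate-education coefficients average to 1.35 and 1.36 within 2
Monte-Carlo SEs (10 replicates in the test suite, 24 in the reproduction
script). One finding worth stating: at this design's event count (~250
acceptances per fit, 8 parameters) the ML country estimate carries the
classic away-from-zero small-sample bias of a few percent; it vanishes when
clusters are enlarged (20–25 respondents per municipality give a mean of
1.354), so it is a property of the 4–5-per-municipality design itself, not
of the fitter.

Test-suite problem sizes are chosen to keep the default run around a minute:
small 60-municipality frames for unit tests, the full design for
calibration-band and recovery checks, 500 replicates for LRT calibration,
and exhaustive enumeration (456 multisets) for the index oracle.

## Known limitations

* County-level spatial structure is an aggregation artifact of municipality
  intercepts; real between-county cultural variation is likely stronger, so
  county-level correlation magnitudes from synthetic data sit at the lower
  end of the observed band.
* The ordinal cut points below the acceptance threshold (−3, −1 and 1.5 on
  the logistic latent) shape the disagree-side distribution and hence PCI
  magnitudes; they are plausible, not fitted to published category counts.
* The Gaussian county models treat mean Likert responses as homoscedastic;
  group sizes vary only mildly (4–5 per municipality), which keeps this
  benign.
* No item-response-theory modelling, no spatial autocorrelation statistics,
  no Bayesian fitting, and no ingestion of real registry data.
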