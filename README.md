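# conflictpci

Analysis toolkit for geographically stratified surveys of attitudes toward
illegal hunting (poaching) of large carnivores — brown bear, wolf, wolverine
and lynx — in Norway and Sweden. It is aimed at human–wildlife-conflict
researchers who want the full pipeline behind such a study as reusable,
tested code: a synthetic survey generator that encodes the sampling design
(4–5 respondents in every one of 709 municipalities), Likert coding, the
Potential Conflict Index, rank-correlation and reliability statistics, and
binomial/Gaussian mixed models with likelihood-ratio backward elimination.

## The statistics at its core

**Potential Conflict Index.** For a group of n centered Likert scores
x_i ∈ {−m, …, +m} (here m = 2), the second-generation index is

    PCI₂ = D / δ,   D = Σ_{pairs i<j, sign(x_i) = −sign(x_j) ≠ 0} |x_i − x_j|,
    δ = ⌊n/2⌋·⌈n/2⌉·2m

so PCI₂ = 0 means consensus and PCI₂ = 1 means half the group at each
extreme. The first-generation variant PCI₁ = 2·min(X_a, X_u)/(n·m), with
X_a and X_u the summed magnitudes of the agreeing and disagreeing sides, is
available behind the same interface.

**Acceptance model.** Respondent-level binarized acceptance
(agree/highly agree vs the rest) follows a binomial-logit mixed model

    logit P(accept) = β₀ + β_country + β_age·age + β_sex + β_edu + u_muni,
    u_muni ~ N(0, σ_u²)

fitted by maximum likelihood (Gauss–Hermite integration of the municipality
intercept), with model selection by backward elimination of
non-significant terms (likelihood-ratio tests, p > 0.05). Spearman
correlations carry the small-sample standard error
SE_r = √((1 − r²)/(n − 2)); reliability uses Cronbach's alpha.

## Worked example

```sh
python examples/01_generate_survey.py
```

```
municipalities: 709   respondents: 3186
counties: 37

Binarized acceptance of poaching (% answering agree/highly agree):
  Norway : bear  9.8%  wolf 10.7%  wolverine 10.5%  lynx 10.2%
  Sweden : bear  2.3%  wolf  2.1%  wolverine  2.1%  lynx  2.3%
```

Norwegian respondents accept poaching several times more often than Swedish
ones; the generator encodes this as a 1.35 log-odds country gap. Fitting the
mixed model back to such a survey (`examples/04_mixed_models.py`) prints,
for seed 42:

```
  country[Norway]                       +1.551 (0.213)
  random-intercept SD (municipality)    0.606

Norway vs Sweden odds ratio: 4.72 (95% CI 3.11-7.16)
```

i.e. the estimate recovers the generating gap within its standard error,
and the odds ratio is the headline "Norwegians are ~4× more likely to find
poaching acceptable" quantity. `examples/02_conflict_index.py` and
`examples/03_reliability_and_correlations.py` walk through the index
decomposition (D, δ, bootstrap CIs) and the reliability/correlation tables;
each prints a line explaining what its numbers mean.

A shell pipeline wraps the same steps:

```sh
conflictpci simulate --out run/
conflictpci analyze --survey run/survey.csv --regions run/regions.csv --out run/analysis
conflictpci report --out run/analysis
```

`analyze` writes the report tables (acceptance percentages with Wilson
intervals, county PCI and its summary, acceptance–PCI correlations at county
and municipality level, inter-species correlations, the mixed-model table
and its elimination trace, reliability coefficients) as CSV.

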