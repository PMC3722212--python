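"""Validation experiments: parameter recovery, reliability calibration,
elimination behavior and likelihood-ratio-test calibration.

These are the replicated simulation studies the package uses to demonstrate
that its estimators recover the quantities its generator encodes.  They are
exercised by the test suite and by the reproduction script, and are importable
for interactive use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GeneratorConfig, SPECIES, SPECIES_ITEMS
from .likert import binarize_acceptance, cronbach_alpha
from .models import ModelSpec, Term, backward_eliminate, fit_glmm, likelihood_ratio_test
from .models import fit_county_lmm
from .synthetic import generate_survey

RECOVERY_SPEC = ModelSpec(
    response="accept",
    family="binomial",
    terms=(
        Term("sex", "sex", "categorical", reference="male"),
        Term("age", "age"),
        Term("education", "education", "categorical", reference="secondary_school"),
        # Sweden as reference so the coefficient is the (positive)
        # Norway-minus-Sweden log-odds gap.
        Term("country", "country", "categorical", reference="Sweden"),
    ),
    group="municipality_id",
)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def equicorrelated_alpha(
    seed: int,
    n_respondents: int = 2522,
    n_items: int = 16,
    rho: float = 0.2615,
    n_seeds: int = 20,
) -> float:
    """Mean standardized Cronbach's alpha of simulated equicorrelated
    continuous item batteries (unit variances, common correlation rho)."""
    alphas = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        common = rng.standard_normal((n_respondents, 1))
        X = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.standard_normal(
            (n_respondents, n_items)
        )
        alphas.append(cronbach_alpha(pd.DataFrame(X), "standardized").alpha)
    return float(np.mean(alphas))


def country_education_recovery(
    seed: int, n_reps: int = 10, config: GeneratorConfig | None = None
) -> pd.DataFrame:
    """Fit the respondent-level binomial mixed model to `n_reps` full-design
    synthetic surveys and collect the country and graduate-education
    coefficients (generator truth: 1.35 and 1.36 on the log-odds scale).

    The response is the binarized bear-poaching item; with a single item per
    respondent the municipality random intercept is the only source of
    within-group dependence, so the likelihood is exactly the generating one.
    """
    base = (config or GeneratorConfig()).to_dict()
    rows = []
    for s in _child_seeds(seed, n_reps):
        survey, regions = generate_survey(GeneratorConfig(**{**base, "seed": s}))
        df = survey.merge(
            regions[["municipality_id", "country"]], on="municipality_id"
        )
        df["accept"] = binarize_acceptance(df["item_6"])
        fit = fit_glmm(df, RECOVERY_SPEC)
        rows.append(
            {
                "seed": s,
                "country": fit.estimate("country[Norway]"),
                "graduate": fit.estimate("education[university_graduate]"),
                "sigma_u": fit.sigma_u,
                "n_obs": fit.n_obs,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def county_acceptance_table(survey: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """County x species table of mean Likert acceptance plus county covariates."""
    df = survey.merge(regions, on="municipality_id")
    parts = []
    for sp, item in SPECIES_ITEMS.items():
        g = (
            df.groupby(["county_id", "country"])[f"item_{item}"]
            .mean()
            .reset_index()
            .rename(columns={f"item_{item}": "mean_accept"})
        )
        g["species"] = sp
        parts.append(g)
    tab = pd.concat(parts, ignore_index=True)
    dens_cols = [f"carnivore_current_{s}" for s in SPECIES] + [
        f"carnivore_historical_{s}" for s in SPECIES
    ]
    dens = regions.drop_duplicates("county_id")[["county_id"] + dens_cols]
    return tab.merge(dens, on="county_id")


def null_density_elimination(seed: int, n_reps: int = 10) -> pd.DataFrame:
    """Backward elimination on county-level models where carnivore densities
    are generated with no effect on acceptance: per replicate, the fraction
    of density terms removed and whether the (real) country effect survived.

    Densities are drawn independently across species here, mirroring the
    pre-modelling collinearity screen that keeps near-duplicate predictors
    out of one model.
    """
    rows = []
    for s in _child_seeds(seed, n_reps):
        cfg = GeneratorConfig(seed=s, carnivore_cross_correlation=0.0)
        survey, regions = generate_survey(cfg)
        tab = county_acceptance_table(survey, regions)
        terms = [
            Term("country", "country", "categorical"),
            Term("species", "species", "categorical"),
        ] + [Term(f"dens_{sp}", f"carnivore_current_{sp}") for sp in SPECIES]
        spec = ModelSpec("mean_accept", "gaussian", tuple(terms), "county_id")
        fit = backward_eliminate(tab, spec)
        kept = {t.name for t in fit.spec.terms}
        n_dens_removed = sum(1 for sp in SPECIES if f"dens_{sp}" not in kept)
        rows.append(
            {
                "seed": s,
                "density_removed_fraction": n_dens_removed / len(SPECIES),
                "country_retained": "country" in kept,
            }
        )
    return pd.DataFrame(rows)


def lrt_null_calibration(
    seed: int, n_reps: int = 500, n_groups: int = 40, group_size: int = 4
) -> np.ndarray:
    """p-values of the LRT for a covariate with no true effect, in a Gaussian
    random-intercept model; approximately Uniform(0, 1) when calibrated."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_reps)
    g = np.repeat(np.arange(n_groups), group_size)
    counties = [f"C{i}" for i in g]
    for rep in range(n_reps):
        u = 0.3 * rng.standard_normal(n_groups)
        df = pd.DataFrame(
            {
                "county": counties,
                "x": rng.standard_normal(len(g)),
                "y": 0.5 + u[g] + 0.2 * rng.standard_normal(len(g)),
            }
        )
        full = fit_county_lmm(df, ModelSpec("y", "gaussian", (Term("x", "x"),), "county"))
        reduced = fit_county_lmm(df, ModelSpec("y", "gaussian", (), "county"))
        pvals[rep] = likelihood_ratio_test(full, reduced).p_value
    return pvals
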