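"""Synthetic survey generator for the geo-stratified carnivore-attitude study.

The generator emulates a two-country, two-level sampling frame (municipalities
nested in counties) with 4-5 telephone respondents per municipality, and an
item battery whose poaching items (6-9) follow a binomial random-intercept
model on the binarized ("agree"/"highly agree") scale.

Response model
--------------
For respondent ``r`` in municipality ``m`` the acceptance propensity is

    eta_r = b0 + b_country * I(Norway) + b_age * age + b_sex * I(female)
            + b_edu(level) + u_m,            u_m ~ N(0, sigma_municipality^2)

Each species item s in {bear, wolf, wolverine, lynx} has latent score

    L_rs = eta_r + q_rs,   q_rs = logit(Phi(Z_rs)),
    Z_rs = sqrt(rho) * F_r + sqrt(1 - rho) * eps_rs,

where ``F_r`` is a shared respondent factor and ``rho`` the species-latent
correlation.  Because Z_rs is standard normal, q_rs is *exactly* standard
logistic, so thresholding L_rs at the fixed third cut point 0 gives

    P(item_s >= 4) = expit(eta_r)

-- the binomial mixed-model truth holds by construction while the full
ordinal distribution (for the conflict index) and the inter-species
correlation remain tunable.  The remaining 12 items come from an
equicorrelated Gaussian battery sharing the factor ``F_r``, thresholded at
standard-normal cut points.

Seeding: a single master seed spawns independent per-stage streams through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))`` with stage 0 =
regions, 1 = demographics, 2 = responses.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .config import (
    BATTERY_ITEMS,
    COUNTRIES,
    EDUCATION_LEVELS,
    GeneratorConfig,
    SPECIES,
    SPECIES_ITEMS,
)

_STAGE_REGIONS = 0
_STAGE_DEMOGRAPHICS = 1
_STAGE_RESPONSES = 2


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def _equicorrelated_normal(
    rng: np.random.Generator, n: int, k: int, rho: float
) -> np.ndarray:
    """n x k standard-normal draws with common pairwise correlation rho."""
    common = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, k))
    return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * noise


def build_regions(config: Optional[GeneratorConfig] = None) -> pd.DataFrame:
    """Build the municipality table with county- and country-level covariates.

    One row per municipality.  Carnivore densities (current and historical)
    are county-level: constant across the municipalities of a county, drawn
    lognormal with a cross-species Gaussian-copula correlation.  The wolf
    zone is a contiguous block of Norwegian municipalities; Sweden has none.
    """
    config = (config or GeneratorConfig()).validate()
    rng = _stage_rng(config.seed, _STAGE_REGIONS)

    frames = []
    for country in COUNTRIES:
        nm = config.n_municipalities[country]
        nc = config.n_counties[country]
        cc = "NO" if country == "Norway" else "SE"

        # Near-equal contiguous county blocks.
        county_of = np.floor(np.arange(nm) * nc / nm).astype(int)
        muni_ids = [f"{cc}-M{i + 1:03d}" for i in range(nm)]
        county_ids = [f"{cc}-C{c + 1:02d}" for c in county_of]

        mu_h, sd_h = config.human_density_lognorm
        human_density = np.exp(mu_h + sd_h * rng.standard_normal(nm))
        big_game = (
            rng.random(nm) < config.big_game_tradition_prob[country]
        ).astype(int)

        if country == "Norway":
            mu_s, sd_s = config.sheep_density_lognorm
            sheep = np.exp(mu_s + sd_s * rng.standard_normal(nm))
            n_zone = int(round(config.wolf_zone_fraction * nm))
            wolf_zone = np.zeros(nm, dtype=int)
            wolf_zone[:n_zone] = 1  # contiguous south-eastern block
        else:
            sheep = np.zeros(nm)
            wolf_zone = np.zeros(nm, dtype=int)

        df = pd.DataFrame(
            {
                "municipality_id": muni_ids,
                "county_id": county_ids,
                "country": country,
                "human_density": human_density,
                "big_game_tradition": big_game,
                "sheep_density": sheep,
                "wolf_zone": wolf_zone,
            }
        )

        # County-level carnivore densities, correlated across species.
        for prefix, (mu_c, sd_c) in (
            ("carnivore_current", config.carnivore_density_lognorm),
            ("carnivore_historical", config.carnivore_hist_density_lognorm),
        ):
            z = _equicorrelated_normal(
                rng, nc, len(SPECIES), config.carnivore_cross_correlation
            )
            dens = np.exp(mu_c + sd_c * z)  # counties x species
            for j, sp in enumerate(SPECIES):
                df[f"{prefix}_{sp}"] = dens[county_of, j]

        frames.append(df)

    return pd.concat(frames, ignore_index=True)


def sample_respondents(
    regions: pd.DataFrame,
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw the respondent skeleton (ids + demographics, no items).

    Per municipality the respondent count is uniform on the configured range;
    sex is Bernoulli(p_female), age uniform on the configured span, education
    categorical.
    """
    if len(regions) == 0:
        raise ValueError("regions table is empty")
    config = (config or GeneratorConfig()).validate()
    rng = _stage_rng(config.seed if seed is None else seed, _STAGE_DEMOGRAPHICS)

    lo, hi = config.respondents_range
    counts = rng.integers(lo, hi + 1, size=len(regions))
    muni = np.repeat(regions["municipality_id"].to_numpy(), counts)
    n = len(muni)

    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    a_lo, a_hi = config.age_range
    age = rng.integers(a_lo, a_hi + 1, size=n)
    education = rng.choice(
        np.array(EDUCATION_LEVELS, dtype=object), size=n, p=config.education_probs
    )

    return pd.DataFrame(
        {
            "respondent_id": [f"R{i + 1:05d}" for i in range(n)],
            "municipality_id": muni,
            "sex": sex,
            "age": age,
            "education": education,
        }
    )


def _linear_predictor(
    skeleton: pd.DataFrame, regions: pd.DataFrame, config: GeneratorConfig
) -> np.ndarray:
    country = skeleton["municipality_id"].map(
        regions.set_index("municipality_id")["country"]
    )
    edu = skeleton["education"].map(dict(config.beta_education)).to_numpy(float)
    return (
        config.intercept
        + config.beta_country * (country == "Norway").to_numpy(float)
        + config.beta_age * skeleton["age"].to_numpy(float)
        + config.beta_sex_female * (skeleton["sex"] == "female").to_numpy(float)
        + edu
    )


def _cut(latent: np.ndarray, cuts) -> np.ndarray:
    """Threshold a latent array into Likert categories 1..5."""
    return 1 + np.searchsorted(np.asarray(cuts), latent, side="left").astype(np.int64)


def generate_responses(
    skeleton: pd.DataFrame,
    regions: pd.DataFrame,
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Fill in the 16 Likert items for a respondent skeleton."""
    config = (config or GeneratorConfig()).validate()
    rng = _stage_rng(config.seed if seed is None else seed, _STAGE_RESPONSES)

    known = set(regions["municipality_id"])
    unknown = ~skeleton["municipality_id"].isin(known)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise ValueError(
            f"unknown municipality_id {skeleton['municipality_id'].iloc[row]!r} "
            f"in skeleton row {row}"
        )

    n = len(skeleton)
    eta = _linear_predictor(skeleton, regions, config)

    # Municipality random intercepts.
    munis = regions["municipality_id"].to_numpy()
    u = dict(zip(munis, config.sigma_municipality * rng.standard_normal(len(munis))))
    eta = eta + skeleton["municipality_id"].map(u).to_numpy(float)

    factor = rng.standard_normal(n)  # shared respondent factor

    survey = skeleton.copy()

    # Poaching items: Gaussian-copula latent with exactly logistic margins.
    rho = config.species_latent_correlation
    eps = rng.standard_normal((n, len(SPECIES)))
    z = np.sqrt(rho) * factor[:, None] + np.sqrt(1.0 - rho) * eps
    # Clip Phi(z) away from {0,1} to keep logit finite.
    q = logit(np.clip(norm.cdf(z), 1e-12, 1.0 - 1e-12))
    latent = eta[:, None] + q
    for j, sp in enumerate(SPECIES):
        survey[f"item_{SPECIES_ITEMS[sp]}"] = _cut(latent[:, j], config.poaching_cuts)

    # General-attitude battery: equicorrelated via the same respondent factor.
    tau = config.item_equicorrelation
    eps_b = rng.standard_normal((n, len(BATTERY_ITEMS)))
    g = np.sqrt(tau) * factor[:, None] + np.sqrt(1.0 - tau) * eps_b
    for j, item in enumerate(BATTERY_ITEMS):
        survey[f"item_{item}"] = _cut(g[:, j], config.battery_cuts)

    item_cols = [f"item_{i}" for i in range(1, 17)]
    survey = survey[list(skeleton.columns) + item_cols]

    if config.missingness > 0:
        mask = rng.random((n, len(item_cols))) < config.missingness
        items = survey[item_cols].to_numpy(float)
        items[mask] = np.nan
        survey[item_cols] = items

    return survey


def generate_survey(
    config: Optional[GeneratorConfig] = None, seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: regions + full survey table from one seed."""
    config = (config or GeneratorConfig()).validate()
    if seed is not None:
        config = GeneratorConfig(**{**config.to_dict(), "seed": seed})
    regions = build_regions(config)
    skeleton = sample_respondents(regions, config)
    survey = generate_responses(skeleton, regions, config)
    return survey, regions
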