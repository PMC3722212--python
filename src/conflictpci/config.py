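"""Configuration objects and shared vocabulary for the survey generator.

The defaults encode the study design this package emulates: a geographically
stratified telephone survey of every Norwegian and Swedish municipality
(4-5 respondents each), sixteen 5-point Likert items of which items 6-9 ask
whether poaching of brown bear, wolf, wolverine and lynx is acceptable, and
region covariates (human density, big-game-hunting tradition, sheep density,
wolf-zone flag, current and historical carnivore densities).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Tuple

COUNTRIES: Tuple[str, str] = ("Norway", "Sweden")

SPECIES: Tuple[str, ...] = ("bear", "wolf", "wolverine", "lynx")

#: Questionnaire item number of each species-specific poaching statement.
SPECIES_ITEMS: Mapping[str, int] = {"bear": 6, "wolf": 7, "wolverine": 8, "lynx": 9}

#: Ordered education levels, lowest first; the first level is the model
#: reference category.
EDUCATION_LEVELS: Tuple[str, ...] = (
    "secondary_school",
    "high_school",
    "university_undergraduate",
    "university_graduate",
)

SEXES: Tuple[str, str] = ("male", "female")

N_ITEMS = 16
LIKERT_MIN, LIKERT_MAX = 1, 5

#: Items 1-5 and 10-16: general carnivore-attitude statements that form the
#: non-poaching part of the battery.
BATTERY_ITEMS: Tuple[int, ...] = tuple(
    i for i in range(1, N_ITEMS + 1) if i not in SPECIES_ITEMS.values()
)


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey generator.

    Fixed-effect defaults are the respondent-level acceptance model estimates
    on the log-odds scale (reference categories: male, secondary school,
    Sweden).  ``beta_country`` is the Norway-minus-Sweden log-odds gap with
    Norway the high-acceptance country.  ``intercept`` is calibrated so the
    country-level binarized acceptance rates fall in the observed ranges
    (Norway ~13%, Sweden ~3.5%) at the default covariate distributions.
    """

    n_municipalities: Mapping[str, int] = field(
        default_factory=lambda: {"Norway": 429, "Sweden": 280}
    )
    n_counties: Mapping[str, int] = field(
        default_factory=lambda: {"Norway": 18, "Sweden": 19}
    )
    respondents_range: Tuple[int, int] = (4, 5)

    # Acceptance process (log-odds scale).
    intercept: float = -4.98
    beta_country: float = 1.35
    beta_age: float = 0.016
    beta_sex_female: float = -0.18
    beta_education: Mapping[str, float] = field(
        default_factory=lambda: {
            "secondary_school": 0.0,
            "high_school": 0.41,
            "university_undergraduate": 0.79,
            "university_graduate": 1.36,
        }
    )
    sigma_municipality: float = 0.5

    # Latent structure of the item battery.
    species_latent_correlation: float = 0.90
    item_equicorrelation: float = 0.30
    #: Latent cut points for the poaching items; the third cut is fixed at 0
    #: so that item >= 4 is exactly the logistic acceptance event.
    poaching_cuts: Tuple[float, float, float, float] = (-3.0, -1.0, 0.0, 1.5)
    #: Standard-normal cut points for the 12 general-attitude items.
    battery_cuts: Tuple[float, float, float, float] = (-1.5, -0.5, 0.5, 1.5)

    # Demographic marginals.
    age_range: Tuple[int, int] = (18, 80)
    p_female: float = 0.5
    education_probs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    # Region covariates.
    big_game_tradition_prob: Mapping[str, float] = field(
        default_factory=lambda: {"Norway": 0.63, "Sweden": 0.23}
    )
    human_density_lognorm: Tuple[float, float] = (2.3, 1.5)
    sheep_density_lognorm: Tuple[float, float] = (1.0, 1.0)
    carnivore_density_lognorm: Tuple[float, float] = (-4.0, 1.0)
    carnivore_hist_density_lognorm: Tuple[float, float] = (-3.0, 1.0)
    #: Gaussian-copula correlation between species' densities; 0.765 makes
    #: the lognormal Spearman correlation ~0.75 (2*sin(pi*0.75/6)).
    carnivore_cross_correlation: float = 0.765
    wolf_zone_fraction: float = 0.10

    missingness: float = 0.0
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        for country in COUNTRIES:
            if country not in self.n_municipalities:
                raise ConfigError(f"n_municipalities missing entry for {country!r}")
            if country not in self.n_counties:
                raise ConfigError(f"n_counties missing entry for {country!r}")
            nm = self.n_municipalities[country]
            nc = self.n_counties[country]
            if nm < 1:
                raise ConfigError(f"n_municipalities[{country!r}] must be >= 1, got {nm}")
            if nc < 1 or nc > nm:
                raise ConfigError(
                    f"n_counties[{country!r}] must be in [1, n_municipalities], got {nc}"
                )
            p = self.big_game_tradition_prob.get(country)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigError(
                    f"big_game_tradition_prob[{country!r}] must be in [0, 1], got {p}"
                )
        lo, hi = self.respondents_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"respondents_range must satisfy 1 <= lo <= hi, got {(lo, hi)}")
        for name in ("p_female", "missingness", "wolf_zone_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.species_latent_correlation <= 1.0:
            raise ConfigError(
                f"species_latent_correlation must be in [0, 1], got "
                f"{self.species_latent_correlation}"
            )
        if not 0.0 <= self.item_equicorrelation < 1.0:
            raise ConfigError(
                f"item_equicorrelation must be in [0, 1), got {self.item_equicorrelation}"
            )
        if not -1.0 / (len(SPECIES) - 1) <= self.carnivore_cross_correlation <= 1.0:
            raise ConfigError(
                f"carnivore_cross_correlation must be a valid equicorrelation, got "
                f"{self.carnivore_cross_correlation}"
            )
        if self.sigma_municipality < 0:
            raise ConfigError(
                f"sigma_municipality must be >= 0, got {self.sigma_municipality}"
            )
        for name in (
            "human_density_lognorm",
            "sheep_density_lognorm",
            "carnivore_density_lognorm",
            "carnivore_hist_density_lognorm",
        ):
            _, scale = getattr(self, name)
            if scale < 0:
                raise ConfigError(f"{name} scale must be >= 0, got {scale}")
        if abs(sum(self.education_probs) - 1.0) > 1e-9 or min(self.education_probs) < 0:
            raise ConfigError(
                f"education_probs must be a probability vector, got {self.education_probs}"
            )
        if set(self.beta_education) != set(EDUCATION_LEVELS):
            raise ConfigError(
                "beta_education must have one entry per education level "
                f"{EDUCATION_LEVELS}"
            )
        if list(self.poaching_cuts) != sorted(self.poaching_cuts):
            raise ConfigError(f"poaching_cuts must be nondecreasing, got {self.poaching_cuts}")
        if list(self.battery_cuts) != sorted(self.battery_cuts):
            raise ConfigError(f"battery_cuts must be nondecreasing, got {self.battery_cuts}")
        ages = self.age_range
        if ages[0] < 0 or ages[1] < ages[0]:
            raise ConfigError(f"age_range must satisfy 0 <= lo <= hi, got {ages}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)
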