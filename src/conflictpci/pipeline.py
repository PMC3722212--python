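"""End-to-end workflow: simulate -> code -> index -> correlate -> model -> report.

`analyze` writes the report tables that mirror the survey study's result
layout: country-level binarized acceptance percentages with Wilson intervals,
county PCI tables and their across-county summaries, acceptance-PCI
correlations at both spatial levels, inter-species correlations, reliability
coefficients, and the respondent-level mixed-model table with its
backward-elimination trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .association import (
    acceptance_pci_correlations,
    acceptance_rates,
    species_acceptance_correlations,
)
from .config import COUNTRIES, GeneratorConfig, SPECIES, SPECIES_ITEMS
from .likert import binarize_acceptance, cronbach_alpha, species_items
from .models import ModelSpec, Term, backward_eliminate, odds_ratio
from .pci import pci_by_group
from .synthetic import build_regions, generate_responses, sample_respondents

logger = logging.getLogger(__name__)

ANALYZE_TABLES = (
    "acceptance_by_country.csv",
    "pci_by_county.csv",
    "pci_summary.csv",
    "correlations_county.csv",
    "correlations_municipality.csv",
    "species_correlations.csv",
    "model_respondent.csv",
    "reliability.csv",
)


@dataclass
class AnalysisConfig:
    pci_variant: str = "pci2"
    elimination_threshold: float = 0.05
    bootstrap_B: int = 1000
    ci_level: float = 0.95
    #: Include the eight county-level carnivore-density covariates in the
    #: respondent model's candidate set (they multiply the elimination cost).
    include_carnivore_terms: bool = True
    country_reference: str = "Norway"


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def run_config_from_dict(raw: dict) -> RunConfig:
    gen = GeneratorConfig(**raw.get("generator", {})).validate()
    ana = AnalysisConfig(**raw.get("analysis", {}))
    if not 0.0 < ana.elimination_threshold < 1.0:
        raise ValueError(
            f"elimination_threshold must be in (0, 1), got {ana.elimination_threshold}"
        )
    return RunConfig(generator=gen, analysis=ana, seed=int(raw.get("seed", 0)))


def simulate(
    config: GeneratorConfig, outdir, seed: Optional[int] = None
) -> tuple[Path, Path]:
    """Generate survey + regions and write them (plus a config echo)."""
    outdir = Path(outdir)
    if seed is not None:
        config = GeneratorConfig(**{**config.to_dict(), "seed": int(seed)})
    config = config.validate()
    regions = build_regions(config)
    skeleton = sample_respondents(regions, config)
    survey = generate_responses(skeleton, regions, config)
    survey_path, regions_path = outdir / "survey.csv", outdir / "regions.csv"
    io.write_table(survey, survey_path)
    io.write_table(regions, regions_path)
    io.write_config_echo(config, config.seed, outdir / "manifest.txt")
    return survey_path, regions_path


def _pci_summary(pci_county: pd.DataFrame, regions: pd.DataFrame, level: float) -> pd.DataFrame:
    """Mean county PCI per species x country with a t-interval across counties."""
    county_country = regions.drop_duplicates("county_id").set_index("county_id")["country"]
    df = pci_county.assign(country=pci_county["group"].map(county_country))
    rows = []
    item_to_species = {v: k for k, v in SPECIES_ITEMS.items()}
    for (country, item), sub in df.groupby(["country", "item"], sort=True):
        vals = sub["value"].dropna().to_numpy()
        k = len(vals)
        mean = float(vals.mean()) if k else np.nan
        if k >= 2 and vals.std(ddof=1) > 0:
            half = stats.t.ppf(0.5 + level / 2, k - 1) * vals.std(ddof=1) / np.sqrt(k)
        else:
            half = 0.0
        rows.append(
            {"country": country, "species": item_to_species[item], "n_counties": k,
             "mean_pci": mean, "ci_low": mean - half, "ci_high": mean + half}
        )
    return pd.DataFrame(rows)


def _stack_species(survey: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Long table: one row per respondent x species with binarized acceptance."""
    base = survey.merge(regions, on="municipality_id", how="left")
    frames = []
    for sp in SPECIES:
        item = f"item_{SPECIES_ITEMS[sp]}"
        sub = base[base[item].notna()].copy()
        sub["species"] = sp
        sub["accept"] = binarize_acceptance(sub[item].astype(int))
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    long["log_human_density"] = np.log(long["human_density"])
    long["log_sheep_density"] = np.log1p(long["sheep_density"])
    return long


def _respondent_model_spec(long: pd.DataFrame, cfg: AnalysisConfig) -> ModelSpec:
    terms = [
        Term("sex", "sex", "categorical", reference="male"),
        Term("age", "age"),
        Term("education", "education", "categorical", reference="secondary_school"),
        Term("species", "species", "categorical"),
        Term("big_game_tradition", "big_game_tradition"),
        Term("log_human_density", "log_human_density"),
    ]
    countries_present = set(long["country"].unique())
    norway_only = countries_present == {"Norway"}
    if len(countries_present) > 1:
        terms.insert(3, Term("country", "country", "categorical",
                             reference=cfg.country_reference))
    if cfg.include_carnivore_terms:
        for sp in SPECIES:
            terms.append(Term(f"current_{sp}", f"carnivore_current_{sp}"))
            terms.append(Term(f"historical_{sp}", f"carnivore_historical_{sp}"))
    if norway_only:
        # Wolf zoning and free-ranging sheep are Norwegian phenomena only.
        terms.append(Term("wolf_zone", "wolf_zone"))
        terms.append(Term("sheep_density", "log_sheep_density"))
    return ModelSpec(
        response="accept",
        family="binomial",
        terms=tuple(terms),
        group="municipality_id",
        forced=frozenset({"sex", "age", "education"}),
    )


def _model_table(fit) -> pd.DataFrame:
    trace = {t["term"]: t for t in fit.elimination_trace if t["action"] == "retained"}
    rows = []
    for name, (est, se) in fit.coefficients.items():
        term = next(
            (t["term"] for t in fit.elimination_trace
             if name == t["term"] or name.startswith(t["term"] + "[")),
            None,
        )
        t = trace.get(term)
        rows.append(
            {"coefficient": name, "estimate": est, "se": se,
             "chi2": t["chi2"] if t else np.nan,
             "df": t["df"] if t else np.nan,
             "p": t["p"] if t else np.nan}
        )
    rows.append(
        {"coefficient": "sigma_municipality", "estimate": fit.sigma_u, "se": np.nan,
         "chi2": np.nan, "df": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


def analyze(
    survey: pd.DataFrame,
    regions: pd.DataFrame,
    outdir,
    config: Optional[AnalysisConfig] = None,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the report tables to `outdir`."""
    cfg = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, pd.DataFrame] = {}

    items = survey[[f"item_{i}" for i in range(1, 17)]]
    poach = species_items(survey)
    rel_rows = []
    for label, tab in (
        ("all_16_items", items),
        ("poaching_items_6_9", poach),
        ("non_poaching_items", items.drop(columns=list(poach.columns.map(
            lambda sp: f"item_{SPECIES_ITEMS[sp]}")))),
    ):
        for variant in ("raw", "standardized"):
            r = cronbach_alpha(tab, variant=variant)
            rel_rows.append(
                {"item_set": label, "variant": variant, "alpha": r.alpha,
                 "n_items": r.n_items, "n_respondents": r.n_respondents}
            )
    out["reliability"] = pd.DataFrame(rel_rows)

    out["acceptance_by_country"] = acceptance_rates(survey, regions)

    pci_county = pci_by_group(survey, regions, "county", variant=cfg.pci_variant)
    out["pci_by_county"] = pci_county
    out["pci_summary"] = _pci_summary(pci_county, regions, cfg.ci_level)

    for level in ("county", "municipality"):
        out[f"correlations_{level}"] = acceptance_pci_correlations(
            survey, regions, level=level, variant=cfg.pci_variant
        )
    out["species_correlations"] = species_acceptance_correlations(survey, regions)

    long = _stack_species(survey, regions)
    spec = _respondent_model_spec(long, cfg)
    fit = backward_eliminate(long, spec, threshold=cfg.elimination_threshold)
    out["model_respondent"] = _model_table(fit)
    out["elimination_trace"] = pd.DataFrame(fit.elimination_trace)

    for name, df in out.items():
        io.write_table(df, outdir / f"{name}.csv")
    return out


def report(outdir) -> str:
    """Headline numbers rendered from a completed analyze() output directory."""
    outdir = Path(outdir)
    needed = ["acceptance_by_country.csv", "correlations_county.csv",
              "model_respondent.csv", "reliability.csv", "pci_summary.csv"]
    for name in needed:
        if not (outdir / name).exists():
            raise FileNotFoundError(
                f"missing analysis output {outdir / name}; run analyze first"
            )
    acc = pd.read_csv(outdir / "acceptance_by_country.csv")
    corr = pd.read_csv(outdir / "correlations_county.csv")
    model = pd.read_csv(outdir / "model_respondent.csv").set_index("coefficient")
    rel = pd.read_csv(outdir / "reliability.csv")
    pci_sum = pd.read_csv(outdir / "pci_summary.csv")

    lines = ["Acceptance of illegal hunting - analysis summary",
             "=" * 48]
    for country in COUNTRIES:
        sub = acc[acc["country"] == country]
        if sub.empty:
            continue
        lines.append(
            f"{country}: binarized acceptance {sub['percent'].min():.1f}-"
            f"{sub['percent'].max():.1f}% across species"
        )
    country_coefs = [c for c in model.index if c.startswith("country[")]
    for name in country_coefs:
        est, se = model.loc[name, "estimate"], model.loc[name, "se"]
        orr = np.exp(est)
        lines.append(
            f"{name}: {est:+.2f} +/- {se:.2f} log-odds "
            f"(odds ratio {orr:.2f}, 95% CI {np.exp(est - 1.96 * se):.2f}-"
            f"{np.exp(est + 1.96 * se):.2f})"
        )
    if not corr.empty and corr["r_sp"].notna().any():
        lines.append(
            "County-level acceptance-PCI Spearman correlations: "
            f"{corr['r_sp'].min():.2f} to {corr['r_sp'].max():.2f}"
        )
    a16 = rel[(rel["item_set"] == "all_16_items") & (rel["variant"] == "raw")]
    if not a16.empty:
        lines.append(f"Cronbach's alpha, all 16 items (raw): {a16['alpha'].iloc[0]:.2f}")
    for country in COUNTRIES:
        sub = pci_sum[pci_sum["country"] == country]
        if sub.empty:
            continue
        lines.append(
            f"{country}: mean county PCI {sub['mean_pci'].min():.2f}-"
            f"{sub['mean_pci'].max():.2f} across species"
        )
    return "\n".join(lines) + "\n"
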