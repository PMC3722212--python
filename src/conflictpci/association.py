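"""Rank correlations (with the small-sample SE convention) and the
multicollinearity screen for region-level predictors.

The standard error attached to a Spearman coefficient follows the classical
Pearson-style convention

    SE_r = sqrt((1 - r^2) / (n - 2))

which reproduces printed survey-table SEs at both county (n ~ 18) and
individual (n ~ 1500) sample sizes; the two-sided p-value uses the matching
t approximation with n - 2 degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import COUNTRIES, SPECIES, SPECIES_ITEMS
from .likert import binarize_acceptance
from .pci import pci_by_group

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    r_sp: float
    se_r: float
    n: int
    p_value: float


def spearman_se(r: float, n: int) -> float:
    """SE of a rank correlation: sqrt((1 - r^2)/(n - 2))."""
    if n <= 2:
        raise ValueError(f"SE undefined for n = {n} (<= 2)")
    return float(np.sqrt(max(0.0, 1.0 - r * r) / (n - 2)))


def spearman_with_se(x, y) -> CorrelationResult:
    """Spearman rank correlation with midrank ties, SE_r and a t-test p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    r = float(stats.spearmanr(x, y).statistic)
    se = spearman_se(r, n)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r, se, n, p)


def _grouped_acceptance(
    survey: pd.DataFrame, regions: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Mean raw Likert level of each poaching item per group, with country."""
    df = survey.merge(
        regions[["municipality_id", "county_id", "country"]],
        on="municipality_id",
        how="left",
    )
    key = {"county": "county_id", "municipality": "municipality_id"}.get(level)
    if key is None:
        raise ValueError(f"level must be 'county' or 'municipality', got {level!r}")
    cols = {sp: f"item_{item}" for sp, item in SPECIES_ITEMS.items()}
    agg = df.groupby([key, "country"], sort=True)[list(cols.values())].mean()
    agg.columns = list(cols)
    return agg.reset_index().rename(columns={key: "group"})


def acceptance_pci_correlations(
    survey: pd.DataFrame,
    regions: pd.DataFrame,
    level: str = "county",
    variant: str = "pci2",
) -> pd.DataFrame:
    """Correlate group mean acceptance with group PCI, per species x country."""
    means = _grouped_acceptance(survey, regions, level)
    pci_tab = pci_by_group(survey, regions, grouping=level, variant=variant)
    rows = []
    for country in COUNTRIES:
        groups = means[means["country"] == country]
        if groups.empty:
            continue
        for sp in SPECIES:
            item = SPECIES_ITEMS[sp]
            sub = pci_tab[pci_tab["item"] == item].set_index("group")["value"]
            merged = groups.set_index("group")[[sp]].join(sub.rename("pci")).dropna()
            try:
                res = spearman_with_se(merged[sp], merged["pci"])
            except ValueError as exc:
                logger.warning(
                    "correlation for %s/%s at %s level failed: %s",
                    country, sp, level, exc,
                )
                rows.append(
                    {"country": country, "species": sp, "level": level,
                     "r_sp": np.nan, "se_r": np.nan, "n": len(merged),
                     "p_value": np.nan}
                )
                continue
            rows.append(
                {"country": country, "species": sp, "level": level,
                 "r_sp": res.r_sp, "se_r": res.se_r, "n": res.n,
                 "p_value": res.p_value}
            )
    return pd.DataFrame(rows)


def species_acceptance_correlations(
    survey: pd.DataFrame, regions: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise inter-species Spearman correlations of the poaching items,
    at the individual-respondent level, per country."""
    df = survey.merge(
        regions[["municipality_id", "country"]], on="municipality_id", how="left"
    )
    rows = []
    for country in COUNTRIES:
        sub = df[df["country"] == country]
        if len(sub) < 3:
            continue
        for sp_a, sp_b in itertools.combinations(SPECIES, 2):
            pair = sub[[f"item_{SPECIES_ITEMS[sp_a]}", f"item_{SPECIES_ITEMS[sp_b]}"]]
            pair = pair.dropna()
            res = spearman_with_se(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append(
                {"country": country, "species_a": sp_a, "species_b": sp_b,
                 "r_sp": res.r_sp, "se_r": res.se_r, "n": res.n,
                 "p_value": res.p_value}
            )
    return pd.DataFrame(rows)


def collinearity_screen(
    predictors: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Spearman matrix of predictors plus the flagged high pairs.

    The default threshold 0.7 treats correlations of the size seen between
    co-occurring carnivore species (~0.75) as too collinear to enter one
    model together.  Constant columns are excluded with a logged note.
    """
    X = pd.DataFrame(predictors)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 predictor columns")
    keep = []
    for col in X.columns:
        if X[col].nunique(dropna=True) <= 1:
            logger.info("collinearity_screen: excluding constant column %r", col)
        else:
            keep.append(col)
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant predictor columns")
    mat = X[keep].corr(method="spearman")
    flags = [
        (a, b, float(mat.loc[a, b]))
        for a, b in itertools.combinations(keep, 2)
        if abs(mat.loc[a, b]) > threshold
    ]
    return mat, flags


def acceptance_rates(survey: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Respondent-level binarized acceptance rate per species x country with a
    95% Wilson score interval, on the percent scale."""
    from statsmodels.stats.proportion import proportion_confint

    df = survey.merge(
        regions[["municipality_id", "country"]], on="municipality_id", how="left"
    )
    rows = []
    for country in COUNTRIES:
        sub = df[df["country"] == country]
        if sub.empty:
            continue
        for sp in SPECIES:
            vals = sub[f"item_{SPECIES_ITEMS[sp]}"].dropna().astype(int)
            acc = binarize_acceptance(vals)
            k, n = int(np.sum(acc)), len(acc)
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            rows.append(
                {"country": country, "species": sp, "n": n,
                 "percent": 100.0 * k / n,
                 "ci_low": 100.0 * lo, "ci_high": 100.0 * hi}
            )
    return pd.DataFrame(rows)
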