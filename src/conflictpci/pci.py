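"""Potential Conflict Index (PCI) for centered Likert scores.

The PCI quantifies how divided a group of ordinal ratings is, on [0, 1]:
0 means full consensus (everyone on one side, or neutral), 1 means maximal
polarization (half the group at each extreme).

Two generations of the index are implemented for scores x_i in {-m..+m}:

``PCI_2`` (default) totals the distances between people on opposite sides:

    D     = sum over unordered pairs {i, j} of |x_i - x_j|
            counted only when sign(x_i) = -sign(x_j) != 0
    delta = floor(n/2) * ceil(n/2) * 2m      (the half-at-each-extreme total)
    PCI_2 = D / delta

Neutral (0) scores pair with nothing but still count toward n through delta.

``PCI_1`` compares the summed magnitudes of the two sides against the
maximum possible sum Z = n*m:

    X_a = sum of positive scores, X_u = sum of |negative scores|
    PCI_1 = 2 * min(X_a, X_u) / (n * m)

which is algebraically (1 - |X_a - X_u| / X) * X / Z with X = X_a + X_u.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import SPECIES_ITEMS
from .likert import recode_centered

logger = logging.getLogger(__name__)

#: Municipality-level groups hold only 4-5 respondents; index values from
#: groups smaller than this are flagged as unstable in `pci_by_group`.
SMALL_GROUP_N = 8


@dataclass(frozen=True)
class PCIResult:
    """A PCI value with its decomposition.

    numerator: D (PCI2) or X - |X_a - X_u| (PCI1);
    maximum:   delta (PCI2) or Z = n*m (PCI1).
    """

    value: float
    variant: str
    n: int
    n_a: int
    n_u: int
    n_neutral: int
    numerator: float
    maximum: float


def _validated_scores(scores, m: int) -> np.ndarray:
    x = np.asarray(scores)
    if x.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    n = len(x)
    if n < 2:
        raise ValueError(f"PCI is undefined for n = {n} (< 2 respondents)")
    if np.any(np.abs(x) > m) or np.any(x != np.floor(x)):
        raise ValueError(f"scores must be integers in -{m}..+{m}")
    return x.astype(np.int64)


def pci2(scores, m: int = 2) -> PCIResult:
    """Second-generation PCI: total opposite-sign pairwise distance / delta."""
    x = _validated_scores(scores, m)
    n = len(x)
    n_a = int((x > 0).sum())
    n_u = int((x < 0).sum())
    if n_a == 0 and n_u == 0:
        logger.info("pci2: all %d responses neutral; index 0 by convention", n)
    # Count-based pair sum: all (positive, negative) value combinations.
    pos_vals, pos_counts = np.unique(x[x > 0], return_counts=True)
    neg_vals, neg_counts = np.unique(x[x < 0], return_counts=True)
    dist = pos_vals[:, None] - neg_vals[None, :]  # always positive
    d = float((pos_counts[:, None] * neg_counts[None, :] * dist).sum())
    delta = (n // 2) * ((n + 1) // 2) * 2 * m
    return PCIResult(d / delta, "pci2", n, n_a, n_u, n - n_a - n_u, d, float(delta))


def pci1(scores, m: int = 2) -> PCIResult:
    """First-generation PCI: 2*min(X_a, X_u) / (n*m)."""
    x = _validated_scores(scores, m)
    n = len(x)
    x_a = float(x[x > 0].sum())
    x_u = float(-x[x < 0].sum())
    z = float(n * m)
    return PCIResult(
        2.0 * min(x_a, x_u) / z,
        "pci1",
        n,
        int((x > 0).sum()),
        int((x < 0).sum()),
        int((x == 0).sum()),
        (x_a + x_u) - abs(x_a - x_u),
        z,
    )


_VARIANTS = {"pci1": pci1, "pci2": pci2}


def pci(scores, variant: str = "pci2", m: int = 2) -> PCIResult:
    if variant not in _VARIANTS:
        raise ValueError(f"unknown PCI variant {variant!r}; use 'pci1' or 'pci2'")
    return _VARIANTS[variant](scores, m=m)


def pci_by_group(
    survey: pd.DataFrame,
    regions: Optional[pd.DataFrame] = None,
    grouping: str = "county",
    items: Optional[Iterable[int]] = None,
    variant: str = "pci2",
) -> pd.DataFrame:
    """One PCI per group per item, pooling all respondents of the group.

    grouping 'municipality' uses the survey's municipality_id; 'county'
    requires the regions table to resolve counties.  Groups with n < 2 get a
    missing value (warned); groups with n < SMALL_GROUP_N are flagged
    ``small_group`` because a handful of respondents cannot pin down a
    divergence index.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown PCI variant {variant!r}")
    if items is None:
        items = sorted(SPECIES_ITEMS.values())
    items = list(items)
    for item in items:
        if f"item_{item}" not in survey.columns:
            raise ValueError(f"unknown item {item!r}: no column item_{item}")

    df = survey
    if grouping == "municipality":
        key = "municipality_id"
    elif grouping == "county":
        if regions is None:
            raise ValueError("county grouping requires the regions table")
        df = survey.merge(
            regions[["municipality_id", "county_id"]], on="municipality_id", how="left"
        )
        key = "county_id"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    for group, sub in df.groupby(key, sort=True):
        for item in items:
            scores = recode_centered(sub[f"item_{item}"].dropna().astype(int))
            if len(scores) < 2:
                logger.warning(
                    "pci_by_group: group %s item %d has n=%d < 2; emitting NaN",
                    group, item, len(scores),
                )
                rows.append(
                    {"group": group, "item": item, "variant": variant,
                     "value": np.nan, "n": len(scores), "n_a": 0, "n_u": 0,
                     "n_neutral": 0, "small_group": True}
                )
                continue
            res = _VARIANTS[variant](scores)
            rows.append(
                {"group": group, "item": item, "variant": variant,
                 "value": res.value, "n": res.n, "n_a": res.n_a, "n_u": res.n_u,
                 "n_neutral": res.n_neutral, "small_group": res.n < SMALL_GROUP_N}
            )
    return pd.DataFrame(rows)


def pci_bootstrap_ci(
    scores,
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    variant: str = "pci2",
    m: int = 2,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a group's PCI (respondent resampling)."""
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    x = _validated_scores(scores, m)
    fn = _VARIANTS[variant]
    if len(np.unique(x)) == 1:
        v = fn(x, m=m).value
        return (v, v)
    rng = np.random.default_rng(seed)
    n = len(x)
    stats = np.empty(B)
    for b in range(B):
        stats[b] = fn(rng.choice(x, size=n, replace=True), m=m).value
    lo, hi = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
    return (float(lo), float(hi))
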