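"""Likert coding and internal-consistency statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SPECIES_ITEMS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    n_items: int
    n_respondents: int
    variant: str  # "raw" or "standardized"


def recode_centered(likert, m: int = 2):
    """Center 1..(2m+1) Likert codes to -m..+m (5-point: 1->-2, 3->0, 5->+2)."""
    x = np.asarray(likert)
    top = 2 * m + 1
    bad = (x < 1) | (x > top) | (x != np.floor(x))
    if bad.any():
        raise ValueError(
            f"Likert value {x[bad].ravel()[0]!r} outside 1..{top}"
        )
    out = x.astype(np.int64) - (m + 1)
    return out if out.ndim else int(out)


def binarize_acceptance(likert):
    """1 for "agree"/"highly agree" (4, 5), 0 for all other answers (1-3)."""
    x = np.asarray(likert)
    bad = (x < 1) | (x > 5) | (x != np.floor(x))
    if bad.any():
        raise ValueError(f"Likert value {x[bad].ravel()[0]!r} outside 1..5")
    out = (x >= 4).astype(np.int64)
    return out if out.ndim else int(out)


def species_items(survey: pd.DataFrame) -> pd.DataFrame:
    """The four poaching items keyed by species name."""
    return pd.DataFrame(
        {sp: survey[f"item_{item}"] for sp, item in SPECIES_ITEMS.items()}
    )


def cronbach_alpha(items: pd.DataFrame, variant: str = "raw") -> ReliabilityResult:
    """Cronbach's alpha of a respondent x item table.

    raw:          (k/(k-1)) * (1 - sum(item variances) / var(total score))
    standardized: k*rbar / (1 + (k-1)*rbar), rbar = mean pairwise correlation

    Rows with any missing value are dropped first (listwise deletion, logged).
    """
    if variant not in ("raw", "standardized"):
        raise ValueError(f"unknown variant {variant!r}")
    X = pd.DataFrame(items)
    k = X.shape[1]
    if k < 2:
        raise ValueError(f"alpha needs >= 2 items, got {k}")
    complete = X.dropna()
    dropped = len(X) - len(complete)
    if dropped:
        logger.info("cronbach_alpha: listwise deletion dropped %d rows", dropped)
    n = len(complete)
    if n < 2:
        raise ValueError(f"alpha needs >= 2 complete respondents, got {n}")
    A = complete.to_numpy(float)
    if variant == "raw":
        total_var = A.sum(axis=1).var(ddof=1)
        if total_var <= 0:
            raise ValueError("total-score variance is zero; alpha undefined")
        alpha = (k / (k - 1)) * (1.0 - A.var(axis=0, ddof=1).sum() / total_var)
    else:
        sd = A.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant item column; standardized alpha undefined")
        R = np.corrcoef(A, rowvar=False)
        rbar = (R.sum() - k) / (k * (k - 1))
        alpha = k * rbar / (1.0 + (k - 1) * rbar)
    return ReliabilityResult(float(alpha), k, n, variant)
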