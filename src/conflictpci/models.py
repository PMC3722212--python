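"""Mixed-model inference for acceptance and conflict responses.

Two model families share one term/specification interface:

* binomial-logit with a random intercept per municipality, fitted by
  maximum likelihood with the random effect integrated out by Gauss-Hermite
  quadrature (the log-likelihoods are therefore directly comparable across
  nested fixed-effect specifications, which the likelihood-ratio backward
  elimination relies on);
* gaussian-identity with a random intercept per county, delegated to
  statsmodels MixedLM with ``reml=False`` for the same reason.

Model terms are declarative: a numeric main effect, a categorical block
(expanded to treatment dummies against a reference level and always dropped
or kept as a whole), or a quadratic block (x and x^2, for the
intermediate-density conflict hypothesis on log human density).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit

logger = logging.getLogger(__name__)

#: Coefficients beyond this magnitude on the logit scale trigger a
#: quasi-separation warning.
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class Term:
    """One model term.

    kind 'numeric': a single column used as-is.
    kind 'categorical': treatment dummies for every level except `reference`
        (default: alphabetically first level); eliminated as a block.
    kind 'quadratic': the column and its square, as one block.
    """

    name: str
    column: str
    kind: str = "numeric"
    reference: Optional[str] = None


@dataclass(frozen=True)
class ModelSpec:
    response: str
    family: str  # "binomial" or "gaussian"
    terms: Tuple[Term, ...]
    group: str
    forced: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate term names in spec")
        missing = self.forced - set(names)
        if missing:
            raise ValueError(f"forced terms not in spec: {sorted(missing)}")

    def drop(self, term_name: str) -> "ModelSpec":
        return replace(
            self, terms=tuple(t for t in self.terms if t.name != term_name)
        )


@dataclass
class ModelFit:
    spec: ModelSpec
    coefficients: Dict[str, Tuple[float, float]]  # name -> (estimate, SE)
    sigma_u: float
    loglik: float
    n_obs: int
    n_groups: int
    n_fixed: int
    converged: bool
    elimination_trace: List[dict] = field(default_factory=list)

    def estimate(self, name: str) -> float:
        return self.coefficients[name][0]

    def se(self, name: str) -> float:
        return self.coefficients[name][1]


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p_value: float


def build_design(
    data: pd.DataFrame, terms: Sequence[Term]
) -> Tuple[np.ndarray, List[str], Dict[str, List[str]]]:
    """Design matrix with intercept; returns (X, column names, term->columns)."""
    n = len(data)
    cols: List[np.ndarray] = [np.ones(n)]
    names: List[str] = ["Intercept"]
    term_cols: Dict[str, List[str]] = {}
    for t in terms:
        if t.column not in data.columns:
            raise ValueError(f"term {t.name!r}: column {t.column!r} not in data")
        if t.kind == "numeric":
            cols.append(data[t.column].to_numpy(float))
            names.append(t.name)
            term_cols[t.name] = [t.name]
        elif t.kind == "quadratic":
            x = data[t.column].to_numpy(float)
            cols.extend([x, x * x])
            block = [t.name, f"{t.name}^2"]
            names.extend(block)
            term_cols[t.name] = block
        elif t.kind == "categorical":
            levels = sorted(data[t.column].astype(str).unique())
            ref = t.reference if t.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(
                    f"term {t.name!r}: reference level {ref!r} not observed"
                )
            block = []
            vals = data[t.column].astype(str).to_numpy()
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((vals == lev).astype(float))
                cname = f"{t.name}[{lev}]"
                names.append(cname)
                block.append(cname)
            term_cols[t.name] = block
        else:
            raise ValueError(f"unknown term kind {t.kind!r}")
    return np.column_stack(cols), names, term_cols


def _glmm_negloglik_grad(params, X, y, starts, group_of_obs, nodes, logw):
    """Negative marginal log-likelihood and gradient for the logit GLMM.

    params = (beta, sigma); the integral over the group intercept uses
    Gauss-Hermite nodes z_k: u_k = sqrt(2)*sigma*z_k.
    """
    beta, sigma = params[:-1], params[-1]
    xb = X @ beta
    u = np.sqrt(2.0) * sigma * nodes  # (K,)
    eta = xb[:, None] + u[None, :]  # (n, K)
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    B = np.add.reduceat(ll_obs, starts, axis=0)  # (G, K)
    M = B + logw[None, :]
    m = M.max(axis=1, keepdims=True)
    S = np.exp(M - m).sum(axis=1)
    ll = float((m[:, 0] + np.log(S)).sum())

    W = np.exp(M - m) / S[:, None]  # posterior node weights per group
    R = y[:, None] - expit(eta)
    WR = W[group_of_obs] * R
    g_beta = X.T @ WR.sum(axis=1)
    g_sigma = float((WR * (np.sqrt(2.0) * nodes)[None, :]).sum())
    grad = np.append(g_beta, g_sigma)
    return -ll, -grad


def fit_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    n_quad: int = 25,
    maxiter: int = 200,
) -> ModelFit:
    """ML fit of a binomial-logit model with one random intercept.

    The marginal likelihood integrates the group intercept with ``n_quad``
    Gauss-Hermite nodes; optimization is bounded L-BFGS-B over (beta, sigma)
    with sigma >= 0, started from the ordinary logistic fit.  Standard errors
    come from the numerically differentiated Hessian at the optimum.
    """
    if spec.family != "binomial":
        raise ValueError("fit_glmm requires a binomial spec")
    if spec.group not in data.columns:
        raise ValueError(f"grouping column {spec.group!r} not in data")
    df = data.sort_values(spec.group, kind="mergesort").reset_index(drop=True)
    y = df[spec.response].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"response {spec.response!r} must be binary 0/1")
    X, names, _ = build_design(df, spec.terms)
    groups = df[spec.group].to_numpy()
    _, starts_idx, group_of_obs = np.unique(
        groups, return_index=True, return_inverse=True
    )
    starts = np.sort(starts_idx)
    n_groups = len(starts)
    if n_groups < 2:
        raise ValueError("need >= 2 groups for a random intercept")

    nodes, weights = hermgauss(n_quad)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    # Start values from the fixed-effects logistic fit.
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            beta0 = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        except Exception:  # fall back to a flat start
            beta0 = np.zeros(X.shape[1])
    x0 = np.append(beta0, 0.3)

    bounds = [(None, None)] * X.shape[1] + [(0.0, None)]
    res = optimize.minimize(
        _glmm_negloglik_grad,
        x0,
        args=(X, y, starts, group_of_obs, nodes, logw),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    params = res.x
    loglik = -float(res.fun)

    # Observed-information SEs via central differences of the gradient.
    k = len(params)
    H = np.zeros((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(params))
    for j in range(k):
        hi, lo = params.copy(), params.copy()
        hi[j] += h[j]
        lo[j] -= h[j]
        _, g_hi = _glmm_negloglik_grad(hi, X, y, starts, group_of_obs, nodes, logw)
        _, g_lo = _glmm_negloglik_grad(lo, X, y, starts, group_of_obs, nodes, logw)
        H[:, j] = (g_hi - g_lo) / (2.0 * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(k, np.nan)

    beta = params[:-1]
    if np.any(np.abs(beta) > SEPARATION_BOUND):
        logger.warning(
            "fit_glmm: coefficient beyond %.0f on the logit scale; "
            "possible separation", SEPARATION_BOUND,
        )
    coeffs = {nm: (float(b), float(s)) for nm, b, s in zip(names, beta, ses[:-1])}
    return ModelFit(
        spec=spec,
        coefficients=coeffs,
        sigma_u=float(params[-1]),
        loglik=loglik,
        n_obs=len(y),
        n_groups=n_groups,
        n_fixed=X.shape[1],
        converged=bool(res.success),
    )


def fit_county_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Gaussian mixed model with a random intercept, via MixedLM (ML)."""
    if spec.family != "gaussian":
        raise ValueError("fit_county_lmm requires a gaussian spec")
    if spec.group not in data.columns:
        raise ValueError(f"grouping column {spec.group!r} not in data")
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = data.reset_index(drop=True)
    y = df[spec.response].to_numpy(float)
    X, names, _ = build_design(df, spec.terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        fit = None
        for method in (["lbfgs", "bfgs"], ["powell"], ["cg"]):
            try:
                model = sm.MixedLM(y, X, groups=df[spec.group])
                fit = model.fit(reml=False, method=method)
                if np.isfinite(fit.llf) and np.all(np.isfinite(fit.bse_fe)):
                    break
                fit = None
            except (np.linalg.LinAlgError, ValueError):
                fit = None
    if fit is None:
        # Random-intercept variance collapsed; the ML fit degenerates to OLS
        # (identical profile log-likelihood at sigma_u = 0).
        ols = sm.OLS(y, X).fit()
        coeffs = {
            nm: (float(est), float(se))
            for nm, est, se in zip(names, ols.params, ols.bse)
        }
        return ModelFit(
            spec=spec, coefficients=coeffs, sigma_u=0.0, loglik=float(ols.llf),
            n_obs=len(y), n_groups=df[spec.group].nunique(),
            n_fixed=X.shape[1], converged=True,
        )
    coeffs = {
        nm: (float(est), float(se))
        for nm, est, se in zip(names, fit.fe_params, fit.bse_fe)
    }
    return ModelFit(
        spec=spec,
        coefficients=coeffs,
        sigma_u=float(np.sqrt(max(0.0, float(np.asarray(fit.cov_re)[0, 0])))),
        loglik=float(fit.llf),
        n_obs=len(y),
        n_groups=df[spec.group].nunique(),
        n_fixed=X.shape[1],
        converged=bool(getattr(fit, "converged", True)),
    )


def fit_model(data: pd.DataFrame, spec: ModelSpec, **kwargs) -> ModelFit:
    if spec.family == "binomial":
        return fit_glmm(data, spec, **kwargs)
    return fit_county_lmm(data, spec)


def likelihood_ratio_test(full: ModelFit, reduced: ModelFit) -> LRTResult:
    """chi2 = 2*(llf_full - llf_reduced) on the fixed-parameter df difference."""
    full_names = {t.name for t in full.spec.terms}
    red_names = {t.name for t in reduced.spec.terms}
    if not red_names < full_names:
        raise ValueError("reduced model terms must be a strict subset of the full model")
    if (
        full.spec.family != reduced.spec.family
        or full.spec.response != reduced.spec.response
        or full.n_obs != reduced.n_obs
    ):
        raise ValueError("models are not nested fits of the same data")
    df_diff = full.n_fixed - reduced.n_fixed
    if df_diff <= 0:
        raise ValueError("full model has no extra parameters")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(chi2, df_diff, float(stats.chi2.sf(chi2, df_diff)))


def backward_eliminate(
    data: pd.DataFrame,
    spec: ModelSpec,
    threshold: float = 0.05,
    **fit_kwargs,
) -> ModelFit:
    """Backward elimination of non-significant terms by likelihood-ratio test.

    Repeatedly refits the model with each non-forced term removed in turn and
    drops the single term with the largest LRT p among those with
    p > threshold (ties broken by term name), until every retained non-forced
    term is significant.  Categorical and quadratic terms leave as blocks.
    The full trace (removed and finally-retained terms) is recorded on the
    returned fit.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    current = spec
    trace: List[dict] = []
    fit = fit_model(data, current, **fit_kwargs)
    while True:
        candidates = [t.name for t in current.terms if t.name not in current.forced]
        if not candidates:
            break
        tests = {}
        for name in sorted(candidates):
            reduced_fit = fit_model(data, current.drop(name), **fit_kwargs)
            tests[name] = likelihood_ratio_test(fit, reduced_fit)
        removable = {n: t for n, t in tests.items() if t.p_value > threshold}
        if not removable:
            for name in sorted(tests):
                t = tests[name]
                trace.append(
                    {"term": name, "chi2": t.chi2, "df": t.df, "p": t.p_value,
                     "action": "retained"}
                )
            break
        # Largest p leaves first; sorted() already fixed the name tie-break.
        drop_name = max(removable, key=lambda n: (removable[n].p_value, n))
        t = removable[drop_name]
        trace.append(
            {"term": drop_name, "chi2": t.chi2, "df": t.df, "p": t.p_value,
             "action": "removed"}
        )
        current = current.drop(drop_name)
        fit = fit_model(data, current, **fit_kwargs)
    fit.elimination_trace = trace
    return fit


def odds_ratio(fit: ModelFit, coefficient: str) -> dict:
    """Odds ratio with a 95% Wald interval for one logit-scale coefficient."""
    if fit.spec.family != "binomial":
        raise ValueError("odds ratios are undefined for a gaussian fit")
    if coefficient not in fit.coefficients:
        raise KeyError(
            f"coefficient {coefficient!r} not in fit "
            f"(have {sorted(fit.coefficients)})"
        )
    est, se = fit.coefficients[coefficient]
    return {
        "OR": float(np.exp(est)),
        "ci_low": float(np.exp(est - 1.96 * se)),
        "ci_high": float(np.exp(est + 1.96 * se)),
    }
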