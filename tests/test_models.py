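"""Mixed models: GLMM likelihood correctness, degenerate-variance agreement
with ordinary GLM, an external lme4 cross-check, LRT and backward
elimination behavior, and odds-ratio extraction."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conflictpci import (
    ModelSpec,
    Term,
    backward_eliminate,
    fit_county_lmm,
    fit_glmm,
    likelihood_ratio_test,
    odds_ratio,
)


def simulate_logistic_clusters(
    rng, n_groups=80, group_size=5, beta=(-1.0, 0.8), sigma=0.5, extra_null=0
):
    """Random-intercept logistic data with one real covariate and optional
    pure-noise covariates."""
    g = np.repeat(np.arange(n_groups), group_size)
    u = sigma * rng.standard_normal(n_groups)
    x = rng.standard_normal(len(g))
    eta = beta[0] + beta[1] * x + u[g]
    df = pd.DataFrame(
        {"group": g, "x": x, "y": (rng.random(len(g)) < expit(eta)).astype(int)}
    )
    for j in range(extra_null):
        df[f"noise{j}"] = rng.standard_normal(len(g))
    return df


def glmm_spec(term_names=("x",), forced=()):
    return ModelSpec(
        response="y",
        family="binomial",
        terms=tuple(Term(t, t) for t in term_names),
        group="group",
        forced=frozenset(forced),
    )


def test_glmm_zero_variance_reduces_to_plain_glm(rng):
    """At sigma_u = 0 the marginal likelihood is exactly the ordinary
    logistic likelihood, and fitting data without clustering stays close to
    the GLM solution (the boundary estimate of sigma is noisy at finite n,
    so only the likelihood identity is exact)."""
    import statsmodels.api as sm
    from numpy.polynomial.hermite import hermgauss

    from conflictpci.models import _glmm_negloglik_grad

    df = simulate_logistic_clusters(rng, n_groups=200, group_size=15, sigma=0.0)
    X = np.column_stack([np.ones(len(df)), df["x"]])
    glm = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()

    d = df.sort_values("group").reset_index(drop=True)
    Xs = np.column_stack([np.ones(len(d)), d["x"]])
    groups = d["group"].to_numpy()
    _, idx, inv = np.unique(groups, return_index=True, return_inverse=True)
    nodes, w = hermgauss(25)
    negll, _ = _glmm_negloglik_grad(
        np.append(glm.params, 0.0), Xs, d["y"].to_numpy(float), np.sort(idx),
        inv, nodes, np.log(w) - 0.5 * np.log(np.pi),
    )
    assert -negll == pytest.approx(glm.llf, abs=1e-6)

    fit = fit_glmm(df, glmm_spec())
    assert fit.sigma_u < 0.25
    assert fit.estimate("Intercept") == pytest.approx(glm.params.iloc[0], abs=0.02)
    assert fit.estimate("x") == pytest.approx(glm.params.iloc[1], abs=0.02)
    assert fit.loglik >= glm.llf - 1e-6  # sigma >= 0 can only help


def test_glmm_parameter_recovery(rng):
    """Mean estimates over replicates stay within 2 MC SEs of the truth."""
    betas = []
    for _ in range(8):
        df = simulate_logistic_clusters(rng, n_groups=150, group_size=6)
        fit = fit_glmm(df, glmm_spec())
        betas.append([fit.estimate("Intercept"), fit.estimate("x"), fit.sigma_u])
    betas = np.asarray(betas)
    for j, truth in enumerate((-1.0, 0.8)):
        mcse = betas[:, j].std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas[:, j].mean() - truth) < 2 * mcse + 1e-9
    assert 0.2 < betas[:, 2].mean() < 0.8  # sigma in a sane band around 0.5


def test_glmm_agrees_with_lme4_oracle(rng):
    """Independent oracle: R lme4::glmer with 25-point adaptive quadrature on
    the same small dataset."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    df = simulate_logistic_clusters(rng, n_groups=60, group_size=6, sigma=0.6)
    fit = fit_glmm(df, glmm_spec())
    with tempfile.TemporaryDirectory() as tmp:
        data_path = Path(tmp) / "d.csv"
        out_path = Path(tmp) / "out.csv"
        df.to_csv(data_path, index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{data_path}")
        m <- glmer(y ~ x + (1 | group), data = d, family = binomial, nAGQ = 25)
        fe <- fixef(m)
        write.csv(data.frame(
            intercept = fe[["(Intercept)"]], x = fe[["x"]],
            sigma = sqrt(unlist(VarCorr(m))[[1]]), loglik = as.numeric(logLik(m))
        ), "{out_path}", row.names = FALSE)
        """
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        if res.returncode != 0:
            pytest.skip(f"lme4 unavailable: {res.stderr[-200:]}")
        ref = pd.read_csv(out_path).iloc[0]
    assert fit.estimate("Intercept") == pytest.approx(ref["intercept"], abs=0.02)
    assert fit.estimate("x") == pytest.approx(ref["x"], abs=0.02)
    assert fit.sigma_u == pytest.approx(ref["sigma"], abs=0.05)
    assert fit.loglik == pytest.approx(ref["loglik"], abs=0.1)


def test_glmm_input_validation(rng):
    df = simulate_logistic_clusters(rng)
    df_bad = df.assign(y=df["y"] + 1)
    with pytest.raises(ValueError, match="binary"):
        fit_glmm(df_bad, glmm_spec())
    with pytest.raises(ValueError, match="grouping"):
        fit_glmm(df.rename(columns={"group": "g"}), glmm_spec())


def county_like_frame(rng, n_counties=37, sigma=0.1, country_effect=0.1,
                      null_covariates=0, noise=0.05):
    """One row per county x species with a Gaussian mean-response."""
    counties = np.arange(n_counties)
    country = np.where(counties < 18, "Norway", "Sweden")
    u = sigma * rng.standard_normal(n_counties)
    rows = []
    for c in counties:
        for sp in ("bear", "wolf", "wolverine", "lynx"):
            rows.append({"county": f"C{c:02d}", "country": country[c],
                         "species": sp, "u": u[c]})
    df = pd.DataFrame(rows)
    df["y"] = (
        0.1
        + country_effect * (df["country"] == "Norway")
        + df["u"]
        + noise * rng.standard_normal(len(df))
    )
    for j in range(null_covariates):
        vals = rng.standard_normal(n_counties)
        df[f"dens{j}"] = vals[pd.factorize(df["county"])[0]]
    return df.drop(columns="u")


def lmm_spec(extra=(), forced=(), quad=()):
    terms = [Term("country", "country", "categorical"),
             Term("species", "species", "categorical")]
    terms += [Term(t, t) for t in extra]
    terms += [Term(t, t, "quadratic") for t in quad]
    return ModelSpec("y", "gaussian", tuple(terms), "county",
                     forced=frozenset(forced))


def test_county_lmm_dimensions(rng):
    df = county_like_frame(rng)
    fit = fit_county_lmm(df, lmm_spec())
    assert fit.n_obs == 148 and fit.n_groups == 37
    assert fit.estimate("country[Sweden]") == pytest.approx(-0.1, abs=0.06)


def test_county_lmm_zero_between_group_variance(rng):
    df = county_like_frame(rng, sigma=0.0, noise=0.1)
    fit = fit_county_lmm(df, lmm_spec())
    assert fit.sigma_u < 0.05


def test_quadratic_peak_gives_negative_second_order(rng):
    """Response peaking at intermediate predictor values fits a negative
    quadratic coefficient (the intermediate-density conflict signature)."""
    n = 200
    x = rng.uniform(-2, 2, n)
    df = pd.DataFrame(
        {"county": [f"C{i % 40}" for i in range(n)],
         "x": x,
         "y": 0.5 - 0.3 * x * x + 0.05 * rng.standard_normal(n)}
    )
    spec = ModelSpec("y", "gaussian", (Term("x", "x", "quadratic"),), "county")
    fit = fit_county_lmm(df, spec)
    assert fit.estimate("x^2") < -0.2


def test_lrt_identical_models_and_nesting(rng):
    df = county_like_frame(rng)
    full = fit_county_lmm(df, lmm_spec())
    with pytest.raises(ValueError):
        likelihood_ratio_test(full, full)  # not strictly nested
    reduced = fit_county_lmm(
        df, ModelSpec("y", "gaussian",
                      (Term("country", "country", "categorical"),), "county")
    )
    res = likelihood_ratio_test(full, reduced)
    assert res.chi2 >= 0 and res.df == 3 and 0 <= res.p_value <= 1


def test_lrt_detects_strong_effect(rng):
    df = county_like_frame(rng, country_effect=0.3)
    full = fit_county_lmm(df, lmm_spec())
    reduced = fit_county_lmm(
        df, ModelSpec("y", "gaussian",
                      (Term("species", "species", "categorical"),), "county")
    )
    assert likelihood_ratio_test(full, reduced).p_value < 1e-6


def test_backward_elimination_all_forced_is_identity(rng):
    df = county_like_frame(rng)
    spec = lmm_spec(forced=("country", "species"))
    fit = backward_eliminate(df, spec)
    assert {t.name for t in fit.spec.terms} == {"country", "species"}
    assert fit.elimination_trace == []


def test_backward_elimination_drops_noise_keeps_signal(rng):
    df = county_like_frame(rng, country_effect=0.3, null_covariates=3)
    spec = lmm_spec(extra=("dens0", "dens1", "dens2"))
    fit = backward_eliminate(df, spec)
    kept = {t.name for t in fit.spec.terms}
    assert "country" in kept
    removed = [t["term"] for t in fit.elimination_trace if t["action"] == "removed"]
    assert len(removed) >= 2  # most noise terms go
    assert all(t["p"] > 0.05 for t in fit.elimination_trace
               if t["action"] == "removed")


def test_odds_ratio_worked_examples():
    spec = glmm_spec()
    fit_stub = lambda est, se: __import__("conflictpci").ModelFit(  # noqa: E731
        spec=spec, coefficients={"x": (est, se)}, sigma_u=0.0, loglik=0.0,
        n_obs=10, n_groups=2, n_fixed=2, converged=True,
    )
    flat = odds_ratio(fit_stub(0.0, 0.2), "x")
    assert flat["OR"] == pytest.approx(1.0)
    assert flat["ci_low"] * flat["ci_high"] == pytest.approx(1.0)

    printed = odds_ratio(fit_stub(1.435, 0.158), "x")
    assert printed["OR"] == pytest.approx(4.2, abs=0.05)
    assert printed["ci_low"] == pytest.approx(3.1, abs=0.05)
    assert printed["ci_high"] == pytest.approx(5.7, abs=0.1)

    assert odds_ratio(fit_stub(1.35, 0.15), "x")["OR"] == pytest.approx(3.86, abs=0.01)

    with pytest.raises(KeyError):
        odds_ratio(fit_stub(0.0, 0.1), "missing")


def test_odds_ratio_rejects_gaussian(rng):
    df = county_like_frame(rng)
    fit = fit_county_lmm(df, lmm_spec())
    with pytest.raises(ValueError, match="gaussian"):
        odds_ratio(fit, "country[Sweden]")
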