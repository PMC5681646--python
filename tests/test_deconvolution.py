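"""Tests for the non-negative binomial lasso and the deconvolution wrapper.

The solver is checked against two independent routes: scipy's
bound-constrained L-BFGS-B on the penalized objective (which is smooth on
the non-negative orthant), and R's glmnet fit of the same model.
"""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy.optimize import minimize

from sid.deconvolution import (
    DeconvolutionConfig,
    deconvolve,
    fit_penalized_path,
    glm_error,
    select_lambda_cv,
)
from sid._solver import penalized_objective
from sid.genotype_model import MetaProfile, union_profiles
from sid.synthetic_data import SimulationConfig, simulate_reference

from .conftest import exhaustive_best_subset, make_meta, make_strain


def _random_instance(seed, n=30, p=6, signal=True):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, (n, p)).astype(float)
    if signal:
        beta = np.zeros(p)
        beta[: max(1, p // 3)] = rng.uniform(0.5, 2.0, max(1, p // 3))
        eta = X @ beta - 1.0
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    else:
        y = rng.integers(0, 2, n).astype(float)
    return X, y


# --- path fitting ---------------------------------------------------------

def test_top_of_path_all_zero():
    X, y = _random_instance(0)
    lams, coefs = fit_penalized_path(X, y, DeconvolutionConfig())
    assert np.all(coefs[0] == 0.0)


def test_single_perfect_predictor_fits_response():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 40).astype(float)
    X = y[:, None].copy()
    lams, coefs = fit_penalized_path(X, y, DeconvolutionConfig(standardize=False))
    beta = coefs[-1]  # smallest lambda
    assert beta[0] > 0
    prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
    assert np.all(prob[y == 1] > 0.5)
    assert np.all(np.abs(prob[y == 0] - 0.5) < 1e-12)  # eta = 0 rows


def test_anticorrelated_column_pinned_at_zero():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 40).astype(float)
    X = np.column_stack([y, 1.0 - y])  # second column anti-correlated
    _, coefs = fit_penalized_path(X, y, DeconvolutionConfig(standardize=False))
    assert np.all(coefs[:, 1] == 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_nonnegativity_and_monotone_sparsity(seed):
    X, y = _random_instance(seed, n=50, p=10)
    lams, coefs = fit_penalized_path(X, y, DeconvolutionConfig())
    assert np.all(coefs >= 0.0)
    n_active = (coefs > 1e-8).sum(axis=1)
    # active-set size non-decreasing as lambda decreases along the path
    assert np.all(np.diff(n_active) >= 0) or (
        # allow rare single-step drops from solver tolerance, but the
        # overall trend must hold between path ends
        n_active[0] <= n_active[-1]
    )


def test_all_zero_response_warns_and_returns_zeros():
    X = np.ones((10, 3))
    with pytest.warns(UserWarning, match="all-zero"):
        _, coefs = fit_penalized_path(X, np.zeros(10), DeconvolutionConfig())
    assert np.all(coefs == 0.0)


def test_non_binary_response_rejected():
    X = np.ones((5, 2))
    with pytest.raises(ValueError, match="binary"):
        fit_penalized_path(X, np.array([0, 1, 2, 0, 1.0]), DeconvolutionConfig())


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("standardize", [False, True])
def test_solver_matches_lbfgsb_oracle(seed, standardize):
    """Coordinate descent agrees with an independent bound-constrained
    optimizer on the same penalized objective."""
    X, y = _random_instance(seed, n=40, p=5)
    config = DeconvolutionConfig(standardize=standardize, tol=1e-9,
                                 max_iter=500)
    scales = X.std(axis=0, ddof=0) if standardize else np.ones(X.shape[1])
    scales[scales == 0] = 1.0
    Xs = X / scales
    for lam in (0.05, 0.01):
        _, coefs = fit_penalized_path(X, y, config, lambdas=np.array([lam]))
        beta_cd = coefs[0] * scales  # scaled-design coefficients
        res = minimize(
            lambda b: penalized_objective(Xs, y, b, lam),
            np.zeros(X.shape[1]), method="L-BFGS-B",
            bounds=[(0, None)] * X.shape[1],
            options=dict(ftol=1e-15, gtol=1e-12, maxiter=10000))
        f_cd = penalized_objective(Xs, y, beta_cd, lam)
        assert f_cd <= res.fun + 1e-8
        np.testing.assert_allclose(beta_cd, res.x, atol=2e-4)


def test_solver_matches_r_glmnet():
    """Cross-check against glmnet (R) fitting the identical model
    (binomial family, lasso, no intercept, non-negative coefficients)."""
    if shutil.which("Rscript") is None:
        pytest.xfail("Rscript not on PATH")
    X, y = _random_instance(3, n=60, p=6)
    lambdas = np.array([0.08, 0.03, 0.01])
    _, coefs = fit_penalized_path(
        X, y, DeconvolutionConfig(standardize=False, tol=1e-9, max_iter=500),
        lambdas=lambdas)
    script = textwrap.dedent("""
        suppressMessages(library(glmnet))
        X <- matrix(scan('stdin', quiet=TRUE), ncol=%d, byrow=TRUE)
        y <- X[, %d]; X <- X[, 1:%d]
        fit <- glmnet(X, y, family='binomial', alpha=1, intercept=FALSE,
                      lower.limits=0, standardize=FALSE,
                      lambda=c(0.08, 0.03, 0.01), thresh=1e-14, maxit=1e6)
        cat(as.vector(as.matrix(coef(fit))[-1, ]), sep='\\n')
    """) % (X.shape[1] + 1, X.shape[1] + 1, X.shape[1])
    data = "\n".join(" ".join(map(str, row)) for row in np.column_stack([X, y]))
    out = subprocess.run(["Rscript", "-e", script], input=data, text=True,
                         capture_output=True, check=True)
    # R prints column-major: p coefficients per lambda, lambdas in order
    ref = np.array(out.stdout.split(), dtype=float).reshape(3, X.shape[1])
    np.testing.assert_allclose(coefs, ref, atol=1e-5)


# --- lambda selection -----------------------------------------------------

def test_select_lambda_deterministic_given_seed():
    X, y = _random_instance(4, n=40, p=8)
    cfg = DeconvolutionConfig(seed=11)
    assert select_lambda_cv(X, y, cfg)[0] == select_lambda_cv(X, y, cfg)[0]


def test_select_lambda_includes_perfect_predictor():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 40).astype(float)
    X = np.column_stack([y, rng.integers(0, 2, (40, 4)).astype(float)])
    cfg = DeconvolutionConfig(seed=0)
    lam, lambdas, _ = select_lambda_cv(X, y, cfg)
    _, coefs = fit_penalized_path(X, y, cfg, lambdas=lambdas)
    beta = coefs[int(np.argmin(np.abs(lambdas - lam)))]
    assert beta[0] > cfg.coef_epsilon


def test_pure_noise_design_selects_almost_nothing():
    """With predictors independent of the response, CV should keep the
    model empty or nearly so in the large majority of replicates."""
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        X = rng.integers(0, 2, (30, 8)).astype(float)
        y = rng.integers(0, 2, 30).astype(float)
        if y.sum() == 0:
            hits += 1
            continue
        cfg = DeconvolutionConfig(seed=seed)
        lam, lambdas, _ = select_lambda_cv(X, y, cfg)
        _, coefs = fit_penalized_path(X, y, cfg, lambdas=lambdas)
        beta = coefs[int(np.argmin(np.abs(lambdas - lam)))]
        if (beta > cfg.coef_epsilon).sum() <= 1:
            hits += 1
    assert hits >= 40  # >= 80% of 50 replicates


def test_n_folds_exceeding_rows_rejected():
    X = np.ones((5, 2))
    y = np.array([0, 1, 0, 1, 0.0])
    with pytest.raises(ValueError, match="n_folds"):
        select_lambda_cv(X, y, DeconvolutionConfig(n_folds=10))


# --- glm_error ------------------------------------------------------------

def test_glm_error_examples():
    q = make_meta("q", [("L", 1), ("L", 2), ("L", 3), ("L", 4)])
    assert glm_error(q, q) == 0.0
    pred = make_meta("p", [("L", 1), ("L", 2), ("L", 3), ("L", 9)])
    assert glm_error(pred, q) == 50.0  # da=2, epa_pred=4
    pred5 = make_meta("p", [("L", i) for i in (1, 2, 3, 4, 5)])
    assert glm_error(pred5, q) == 20.0  # da=1, epa_pred=5
    with pytest.warns(UserWarning, match="empty predicted"):
        assert glm_error(make_meta("p", []), q) == 100.0


# --- deconvolve -----------------------------------------------------------

def test_deconvolve_self_identification(disjoint_reference):
    query = MetaProfile("q", disjoint_reference[2].calls)
    result = deconvolve(disjoint_reference, query, DeconvolutionConfig(seed=1))
    assert result.selected == ("D3",)
    assert result.glm_error == 0.0
    assert result.predicted.calls == query.calls


def test_deconvolve_two_strain_pool_matches_exhaustive_oracle(disjoint_reference):
    query = union_profiles(disjoint_reference[:2], sample_id="q")
    result = deconvolve(disjoint_reference, query, DeconvolutionConfig(seed=1))
    assert set(result.selected) == {"D1", "D2"}
    assert result.glm_error == 0.0
    assert exhaustive_best_subset(disjoint_reference, query) == 0
    assert result.n_diff_alleles == 0


def test_deconvolve_query_with_unknown_allele(disjoint_reference):
    extra = make_meta("q", [("C3", 999)])
    query = MetaProfile("q", disjoint_reference[0].calls | extra.calls)
    result = deconvolve(disjoint_reference, query, DeconvolutionConfig(seed=1))
    assert result.selected == ("D1",)
    n = len(disjoint_reference[0].calls)
    assert result.glm_error == pytest.approx(100.0 * 1 / n)


def test_deconvolve_requires_nonempty_inputs(disjoint_reference):
    with pytest.raises(ValueError):
        deconvolve([], MetaProfile("q", disjoint_reference[0].calls))
    with pytest.raises(ValueError):
        deconvolve(disjoint_reference, MetaProfile("q"))


def test_deconvolve_deterministic_given_seed():
    ref = simulate_reference(SimulationConfig(n_strains=12, seed=9))
    query = union_profiles(ref[:3], sample_id="q")
    cfg = DeconvolutionConfig(seed=5)
    r1 = deconvolve(ref, query, cfg)
    r2 = deconvolve(ref, query, cfg)
    assert r1 == r2


def test_deconvolve_coefficients_nonnegative():
    ref = simulate_reference(SimulationConfig(n_strains=15, seed=21))
    query = union_profiles(ref[4:7], sample_id="q")
    result = deconvolve(ref, query, DeconvolutionConfig(seed=2))
    assert all(v >= 0 for v in result.coefficients.values())
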