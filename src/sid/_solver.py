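"""Coordinate-descent solver for the non-negative binomial lasso.

Minimises, over beta >= 0 and without an intercept,

    (1/n) * sum_i [ log(1 + exp(x_i . beta)) - y_i * (x_i . beta) ]
        + lambda * sum_j beta_j

for a decreasing sequence of lambda values, with warm starts along the
path.  Because the coefficients are constrained non-negative the L1
penalty is linear on the feasible set, so the coordinate update is a
soft-threshold followed by projection onto [0, inf).

The algorithm is the standard penalized-IRLS scheme: an outer loop forms
the weighted quadratic approximation of the binomial log-likelihood at
the current coefficients (weights w = mu(1-mu), working response
z = eta + (y-mu)/w) and an inner loop runs cyclic coordinate descent on
that weighted least-squares problem, alternating full sweeps with cheap
sweeps over the active set only.  Weights are floored at 1e-5 and the
linear predictor is clipped at +/-30 before the logistic transform to
keep the quadratic approximation finite for separable fits.

Design columns here come from scaled presence/absence profiles, so each
column holds a single repeated nonzero value; the kernel exploits that
sparsity (per-column nonzero row lists) to make sweep cost proportional
to the number of allele calls rather than to rows x strains.

Compiled with numba; the kernel is deterministic (no RNG, fixed sweep
order).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# floor on IRLS weights mu*(1-mu); glmnet uses a similar guard
_WEIGHT_FLOOR = 1e-5
_ETA_CLIP = 30.0


@njit(cache=True)
def _cd_sweep(nzptr, nzrow, colval, w, r, eta, beta, lam, n,
              active_only):  # pragma: no cover
    """One cyclic coordinate-descent sweep; returns max coefficient change.

    Columns are given in compressed form: column j occupies
    ``nzrow[nzptr[j]:nzptr[j+1]]`` with the constant entry ``colval[j]``.
    """
    p = colval.shape[0]
    maxdiff = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        v = colval[j]
        if v == 0.0:
            continue
        num = 0.0
        den = 0.0
        for k in range(nzptr[j], nzptr[j + 1]):
            i = nzrow[k]
            num += w[i] * (r[i] + v * bj)
            den += w[i]
        num = num * v / n
        den = den * v * v / n
        if den <= 0.0:
            newb = 0.0
        else:
            newb = (num - lam) / den
            if newb < 0.0:
                newb = 0.0
        d = newb - bj
        if d != 0.0:
            vd = v * d
            for k in range(nzptr[j], nzptr[j + 1]):
                i = nzrow[k]
                r[i] -= vd
                eta[i] += vd
            beta[j] = newb
            # weighted squared-change criterion (the glmnet convention):
            # a move along a direction with vanishing curvature does not
            # count as progress
            wd = den * d * d
            if wd > maxdiff:
                maxdiff = wd
    return maxdiff


@njit(cache=True)
def nn_binomial_lasso_path(X, y, lambdas, max_iter, tol):  # pragma: no cover
    """Fit the non-negative lasso path; returns (n_lambda, p) coefficients.

    ``X`` (n, p) float64 with at most one distinct nonzero value per
    column (a scaled presence/absence design), ``y`` (n,) float64 in
    {0,1}, ``lambdas`` decreasing.  ``max_iter`` bounds the outer IRLS
    iterations per lambda; ``tol`` is the convergence threshold on the
    largest curvature-weighted squared coefficient change
    (max_j den_j * delta_j^2) seen in one outer iteration.
    """
    n, p = X.shape
    nl = lambdas.shape[0]
    coefs = np.zeros((nl, p))
    beta = np.zeros(p)
    eta = np.zeros(n)
    mu = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)

    # compressed per-column nonzero structure
    nnz = 0
    for j in range(p):
        for i in range(n):
            if X[i, j] != 0.0:
                nnz += 1
    nzptr = np.empty(p + 1, dtype=np.int64)
    nzrow = np.empty(nnz, dtype=np.int64)
    colval = np.zeros(p)
    pos = 0
    for j in range(p):
        nzptr[j] = pos
        for i in range(n):
            if X[i, j] != 0.0:
                nzrow[pos] = i
                colval[j] = X[i, j]
                pos += 1
    nzptr[p] = pos

    for li in range(nl):
        lam = lambdas[li]
        for _outer in range(max_iter):
            # quadratic approximation at the current beta
            for i in range(n):
                e = eta[i]
                if e > _ETA_CLIP:
                    e = _ETA_CLIP
                elif e < -_ETA_CLIP:
                    e = -_ETA_CLIP
                m = 1.0 / (1.0 + np.exp(-e))
                mu[i] = m
                wi = m * (1.0 - m)
                if wi < _WEIGHT_FLOOR:
                    wi = _WEIGHT_FLOOR
                w[i] = wi
                r[i] = (y[i] - mu[i]) / wi  # working residual z - eta

            outer_maxdiff = 0.0
            # full sweeps alternate with active-set-only sweeps
            for _cycle in range(50):
                maxdiff = _cd_sweep(nzptr, nzrow, colval, w, r, eta, beta,
                                    lam, n, False)
                if maxdiff > outer_maxdiff:
                    outer_maxdiff = maxdiff
                if maxdiff < tol:
                    break
                for _inner in range(1000):
                    adiff = _cd_sweep(nzptr, nzrow, colval, w, r, eta, beta,
                                      lam, n, True)
                    if adiff > outer_maxdiff:
                        outer_maxdiff = adiff
                    if adiff < tol:
                        break
            if outer_maxdiff < tol:
                break
        coefs[li, :] = beta
    return coefs


def penalized_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                        lam: float) -> float:
    """Value of the penalized mean negative log-likelihood (test oracle aid)."""
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    nll = np.mean(np.log1p(np.exp(eta)) - y * eta)
    return float(nll + lam * np.sum(np.abs(beta)))
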