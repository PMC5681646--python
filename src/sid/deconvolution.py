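"""Strain deconvolution of SSR meta-profiles by a non-negative lasso GLM.

The model treats the allele universe as observations: row i of the design
matrix records which reference strains carry allele i (0/1), and the
response y_i records whether the query sample shows allele i.  A binomial
GLM with no intercept, L1 (lasso) penalty and non-negativity constraint
on the coefficients is fit along a regularization path; the penalty
weight lambda is chosen by cross-validation over universe rows
(minimising mean squared error of the predicted presence probabilities,
by default).  Strains with a non-zero coefficient at the chosen lambda
are called present.

The non-negativity constraint encodes the physics of pooling: a strain
can only *add* alleles to a sample, never remove them.  Together with the
lasso it yields a sparse, additive explanation of the observed allele
set.  Coefficient magnitudes are selection scores, not strain
frequencies.

The fit is scored by the model error

    glm_error = 100 * |predicted  symm-diff  query| / |predicted|

where *predicted* is the union of the called strains' profiles -- the
percentage of alleles differing between prediction and query, relative
to the predicted profile's size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._solver import nn_binomial_lasso_path
from .genotype_model import (
    BinaryMatrix,
    MetaProfile,
    StrainProfile,
    build_universe,
    encode,
    profile_difference,
    union_profiles,
)

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionResult",
    "fit_penalized_path",
    "select_lambda_cv",
    "deconvolve",
    "glm_error",
]


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Solver and cross-validation settings for the penalized GLM.

    Parameters
    ----------
    n_folds
        Cross-validation folds over universe rows (alleles).
    cv_metric
        ``"mse"`` scores held-out rows by squared error of the predicted
        presence probability; ``"deviance"`` by binomial deviance.
    lambda_path_size, lambda_min_ratio
        Length and span of the log-spaced lambda path: from the smallest
        lambda at which all coefficients are zero down to
        ``lambda_min_ratio`` times that value.
    seed
        Seed for the fold-assignment RNG; fixes the whole result.
    coef_epsilon
        Coefficients above this threshold count as "non-zero" (a strain
        call).
    standardize
        Scale design columns to unit variance before fitting (columns are
        not centred: the model has no intercept).  Reported coefficients
        are always on the original 0/1 scale.
    max_iter, tol
        Outer IRLS iteration cap and convergence threshold per lambda.
        Convergence is declared when the largest curvature-weighted
        squared coefficient change of a sweep falls below ``tol`` (the
        convention of coordinate-descent GLM solvers: a move along a
        direction of vanishing curvature does not count as progress).
    """

    n_folds: int = 10
    cv_metric: str = "mse"
    lambda_path_size: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int = 0
    coef_epsilon: float = 1e-8
    standardize: bool = True
    max_iter: int = 100
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.cv_metric not in ("mse", "deviance"):
            raise ValueError(f"unknown cv_metric {self.cv_metric!r}")
        if not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.coef_epsilon <= 0:
            raise ValueError("coef_epsilon must be > 0")
        if self.lambda_path_size < 2:
            raise ValueError("lambda_path_size must be >= 2")


@dataclass(frozen=True)
class DeconvolutionResult:
    """Outcome of one deconvolution: called strains and fit diagnostics."""

    selected: tuple[str, ...]
    coefficients: Mapping[str, float]
    lambda_chosen: float
    predicted: MetaProfile
    glm_error: float
    n_predicted_alleles: int
    n_diff_alleles: int
    empty_prediction: bool = False


def _as_design(X) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, BinaryMatrix):
        return X.values, X.strain_ids
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("design matrix must be a 0/1 presence/absence matrix")
    return arr, None


def _check_response(y, n_rows: int) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.shape[0] != n_rows:
        raise ValueError(f"response length {y.shape[0]} != design rows {n_rows}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    return y


def _column_scales(X: np.ndarray, standardize: bool) -> np.ndarray:
    if not standardize:
        return np.ones(X.shape[1])
    s = X.std(axis=0, ddof=0)
    s[s == 0.0] = 1.0  # constant columns: leave unscaled (coef stays 0 anyway)
    return s


def lambda_path(X: np.ndarray, y: np.ndarray, config: DeconvolutionConfig,
                scales: np.ndarray | None = None) -> np.ndarray:
    """Log-spaced lambda sequence from lambda_max down.

    ``lambda_max`` is the smallest penalty at which every coefficient is
    zero.  Under the non-negativity constraint only coordinates with a
    negative gradient of the unpenalized loss at beta = 0 can activate,
    so lambda_max = max_j (x_j . (y - 1/2)) / n over the (scaled) design,
    clipped below at a tiny positive value.
    """
    if scales is None:
        scales = _column_scales(X, config.standardize)
    n = X.shape[0]
    grad = (X / scales).T @ (y - 0.5) / n
    lam_max = float(np.max(grad, initial=0.0))
    if lam_max <= 0.0:
        # no coordinate can ever activate; degenerate but well-defined path
        lam_max = 1e-3
    return lam_max * np.logspace(
        0.0, np.log10(config.lambda_min_ratio), config.lambda_path_size)


def fit_penalized_path(X, y, config: DeconvolutionConfig | None = None,
                       lambdas: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Fit the non-negative binomial lasso along a lambda path.

    Returns ``(lambdas, coefs)`` with ``coefs`` of shape
    ``(len(lambdas), p)`` on the original (unscaled) design scale.
    """
    config = config or DeconvolutionConfig()
    Xv, _ = _as_design(X)
    if Xv.shape[1] < 1:
        raise ValueError("design matrix needs at least one column")
    y = _check_response(y, Xv.shape[0])
    scales = _column_scales(Xv, config.standardize)
    if lambdas is None:
        lambdas = lambda_path(Xv, y, config, scales)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if np.all(y == 0.0):
        warnings.warn("response is all-zero: no strain can be called",
                      stacklevel=2)
        return lambdas, np.zeros((lambdas.shape[0], Xv.shape[1]))
    coefs_scaled = nn_binomial_lasso_path(
        np.ascontiguousarray(Xv / scales), y, lambdas,
        config.max_iter, config.tol)
    return lambdas, coefs_scaled / scales  # back to the original 0/1 scale


def _cv_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def _path_deviance(X: np.ndarray, y: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    eta = np.clip(X @ coefs.T, -30.0, 30.0)
    return np.mean(np.log1p(np.exp(eta)) - y[:, None] * eta, axis=0)


def select_lambda_cv(X, y, config: DeconvolutionConfig | None = None
                     ) -> tuple[float, np.ndarray, np.ndarray]:
    """Choose lambda by seeded K-fold cross-validation over universe rows.

    Returns ``(lambda_chosen, lambdas, mean_cv_score)``.  Folds are an
    unstratified seeded partition of the rows; each fold's model is fit
    on the remaining rows over the full-data lambda sequence, and scored
    on the held-out rows.  Ties in the CV curve resolve to the largest
    (sparsest) lambda.  Folds whose training rows are all one class still
    contribute their score; if every fold degenerates this way, lambda
    falls back to the full-path deviance minimiser with a warning.
    """
    config = config or DeconvolutionConfig()
    Xv, _ = _as_design(X)
    y = _check_response(y, Xv.shape[0])
    n = Xv.shape[0]
    if config.n_folds > n:
        raise ValueError(
            f"n_folds={config.n_folds} exceeds the number of rows ({n})")
    scales = _column_scales(Xv, config.standardize)
    lambdas = lambda_path(Xv, y, config, scales)
    folds = _cv_folds(n, config.n_folds, config.seed)

    scores = np.zeros((len(folds), len(lambdas)))
    n_degenerate = 0
    for k, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        X_tr, y_tr = Xv[mask], y[mask]
        X_te, y_te = Xv[test_idx], y[test_idx]
        if len(np.unique(y_tr)) < 2:
            n_degenerate += 1
        _, coefs = fit_penalized_path(X_tr, y_tr, config, lambdas=lambdas)
        eta = np.clip(X_te @ coefs.T, -30.0, 30.0)  # (n_te, n_lambda)
        prob = 1.0 / (1.0 + np.exp(-eta))
        if config.cv_metric == "mse":
            scores[k] = np.mean((prob - y_te[:, None]) ** 2, axis=0)
        else:
            scores[k] = np.mean(
                np.log1p(np.exp(eta)) - y_te[:, None] * eta, axis=0)
    if n_degenerate == len(folds):
        warnings.warn(
            "all CV folds degenerate (single-class training rows); "
            "choosing lambda by full-path deviance", stacklevel=2)
        _, coefs_full = fit_penalized_path(Xv, y, config, lambdas=lambdas)
        dev = _path_deviance(Xv, y, coefs_full)
        best = int(np.argmin(dev))
        return float(lambdas[best]), lambdas, dev
    mean_score = scores.mean(axis=0)
    best = int(np.argmin(mean_score))  # lambdas descend: argmin -> largest lambda
    return float(lambdas[best]), lambdas, mean_score


def glm_error(predicted: MetaProfile, query: MetaProfile) -> float:
    """Model error: percent of differing alleles relative to prediction size.

    ``100 * |predicted symm-diff query| / |predicted|``; zero iff the
    union of the called strains' profiles reproduces the query exactly.
    An empty prediction makes the ratio undefined; 100.0 is returned
    (with a warning) so batch benchmarks stay total.
    """
    diff = profile_difference(predicted, query)
    if diff.n_a == 0:
        warnings.warn("empty predicted profile: glm_error undefined, "
                      "reporting 100.0", stacklevel=2)
        return 100.0
    return 100.0 * diff.n_diff / diff.n_a


def deconvolve(reference: Sequence[StrainProfile], query: MetaProfile,
               config: DeconvolutionConfig | None = None
               ) -> DeconvolutionResult:
    """Identify which reference strains compose a query meta-profile.

    Builds the allele universe over reference plus query (query-only
    alleles become unexplainable rows), encodes both, fits the penalized
    path, picks lambda by cross-validation, and calls every strain whose
    coefficient exceeds ``config.coef_epsilon``.
    """
    config = config or DeconvolutionConfig()
    if not reference:
        raise ValueError("reference collection is empty")
    if not query.calls:
        raise ValueError("query meta-profile is empty")
    universe = build_universe(reference, extra=query)
    X = BinaryMatrix.from_profiles(reference, universe)
    y = encode(query, universe)

    lam, lambdas, _ = select_lambda_cv(X, y, config)
    _, coefs = fit_penalized_path(X, y, config, lambdas=lambdas)
    beta = coefs[int(np.argmin(np.abs(lambdas - lam)))]

    selected = tuple(sid for sid, b in zip(X.strain_ids, beta)
                     if b > config.coef_epsilon)
    coefficients = {sid: float(b) for sid, b in zip(X.strain_ids, beta)
                    if b > 0.0}
    if selected:
        sel_profiles = [p for p in reference if p.strain_id in set(selected)]
        predicted = union_profiles(sel_profiles, sample_id=f"{query.sample_id}:predicted")
        err = glm_error(predicted, query)
        empty = False
    else:
        predicted = MetaProfile(f"{query.sample_id}:predicted", frozenset())
        err = 100.0
        empty = True
    diff = profile_difference(predicted, query)
    return DeconvolutionResult(
        selected=selected,
        coefficients=coefficients,
        lambda_chosen=lam,
        predicted=predicted,
        glm_error=err,
        n_predicted_alleles=diff.n_a,
        n_diff_alleles=diff.n_diff,
        empty_prediction=empty,
    )
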