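"""Logistic regression engine for sign outcomes.

Sign outcomes take values in {0, 0.5, 1}; ties (0.5) are handled by
evaluating the Bernoulli log-likelihood at the fractional response, which
preserves the estimating-equation mean structure E[I] = expit(x'beta).

Maximum likelihood is fitted by Newton-Raphson from beta = 0.  Complete or
quasi-complete separation — the group indicator perfectly predicting the
outcome — makes ML estimates infinite; it is detected from diverging
coefficients or saturated fitted probabilities, and resolved by refitting
with Firth's bias-reduced penalised likelihood l(beta) + 0.5 log det I(beta),
whose estimates are always finite for a full-rank design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

MAX_ITER = 50
SCORE_TOL = 1e-8
BETA_CAP = 15.0
PROB_TOL = 1e-8


class GLMError(ValueError):
    pass


@dataclass
class GLMFit:
    coefficients: np.ndarray
    covariance: np.ndarray
    converged: bool
    firth_used: bool = False
    n_iter: int = 0
    separated: bool = False
    names: list[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


def _check_design(y: np.ndarray, X: np.ndarray) -> None:
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise GLMError("responses must lie in [0, 1]")
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise GLMError("design matrix shape does not match responses")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise GLMError("design matrix is rank deficient")


def _loglik(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic_ml(y, X, names: list[str] | None = None) -> GLMFit:
    """Newton-Raphson ML fit of logit(E[y]) = X beta with fractional y.

    Non-convergence or divergence is flagged (``converged``/``separated``),
    never silent; the covariance is the inverse observed information at the
    final iterate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(y, X)
    k = X.shape[1]
    beta = np.zeros(k)
    converged = False
    separated = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        eta = X @ beta
        p = expit(eta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = p * (1 - p)
        info = X.T @ (X * np.maximum(w, 1e-10)[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > BETA_CAP:
            separated = True
            break
    p = expit(X @ beta)
    if not separated:
        # quasi-separation: saturated fitted probabilities at non-tied points
        informative = (y != 0.5)
        if informative.any() and np.all(
            (p[informative] < PROB_TOL) | (p[informative] > 1 - PROB_TOL)
        ):
            separated = True
    w = np.maximum(p * (1 - p), 1e-10)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return GLMFit(
        coefficients=beta,
        covariance=cov,
        converged=converged and not separated,
        firth_used=False,
        n_iter=n_iter,
        separated=separated,
        names=list(names or []),
    )


def detect_separation(y, X) -> bool:
    """True when the ML path diverges (infinite-estimate geometry)."""
    fit = fit_logistic_ml(y, X)
    return fit.separated


def _firth_penalised_loglik(y, X, beta):
    p = expit(X @ beta)
    w = np.maximum(p * (1 - p), 1e-12)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return _loglik(y, p) + 0.5 * logdet


def fit_logistic_firth(y, X, names: list[str] | None = None) -> GLMFit:
    """Firth's bias-reduced logistic fit (penalised Newton with step-halving).

    The modified score is X' (y - p + h (0.5 - p)) with h the leverages of
    the weighted hat matrix; estimates are finite even under separation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(y, X)
    k = X.shape[1]
    beta = np.zeros(k)
    ll = _firth_penalised_loglik(y, X, beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        p = expit(X @ beta)
        w = np.maximum(p * (1 - p), 1e-12)
        info = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise GLMError("singular information in Firth fit") from exc
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        step = info_inv @ score
        # step-halving on the penalised likelihood
        for _ in range(20):
            cand = beta + step
            ll_new = _firth_penalised_loglik(y, X, cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
        beta = beta + step
        ll = _firth_penalised_loglik(y, X, beta)
    if not converged:
        raise GLMError(f"Firth fit did not converge in {MAX_ITER} iterations")
    p = expit(X @ beta)
    w = np.maximum(p * (1 - p), 1e-12)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    return GLMFit(
        coefficients=beta,
        covariance=cov,
        converged=True,
        firth_used=True,
        n_iter=n_iter,
        names=list(names or []),
    )


def fit_logistic(y, X, firth: str = "auto", names: list[str] | None = None) -> GLMFit:
    """Policy fit: ML first, Firth fallback on separation/non-convergence.

    ``firth``: "auto" (fallback), "always", or "never".
    """
    if firth not in ("auto", "always", "never"):
        raise GLMError(f"unknown firth policy {firth!r}")
    if firth == "always":
        return fit_logistic_firth(y, X, names=names)
    fit = fit_logistic_ml(y, X, names=names)
    if firth == "auto" and (fit.separated or not fit.converged):
        return fit_logistic_firth(y, X, names=names)
    return fit
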