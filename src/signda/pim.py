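"""Probabilistic index models (PIMs) on R-sign pseudo-observations.

A PIM regresses the pairwise comparison probability
P{N/R <= N*/R* | Z} = expit(Z' beta) on antisymmetric pair covariates
Z_ij = (A_j - A_i, L_j - L_i, ...).  The coefficients solve the estimating
equation

    U(beta) = sum_pairs Z_ij (I_ij - expit(Z_ij' beta)) = 0,

fitted by Newton iteration.  Because pseudo-observations sharing a sample
index are dependent, the variance is the U-statistic sandwich
A^-1 B A^-T, with A the derivative of U and B summing residual
cross-products over couples of pairs that share at least one sample.

Each unordered pair is retained once (oriented i < j); the reverse
orientation is redundant because (I_ji, Z_ji) = (1 - I_ij, -Z_ij) gives an
identical score contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .io import SampleMetadata
from .signs import RSignMatrix

MAX_ITER = 50
SCORE_TOL = 1e-8
BETA_CAP = 15.0


class PIMError(ValueError):
    pass


@dataclass
class PIMDesign:
    pairs: np.ndarray        # (P, 2) sample indices, i < j
    pseudo_obs: np.ndarray   # (P,) I_ij values in {0, 0.5, 1}
    Z: np.ndarray            # (P, k) antisymmetric pair covariates
    n_samples: int
    names: list[str] = field(default_factory=list)


@dataclass
class PIMFit:
    coefficients: np.ndarray
    covariance: np.ndarray
    converged: bool
    n_iter: int = 0
    degenerate: bool = False
    names: list[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


def build_pim_design(
    rsigns: RSignMatrix,
    meta: SampleMetadata,
    covariate_names: list[str] | None = None,
    marginal: bool = False,
) -> PIMDesign:
    """Pair design from an R-sign matrix and sample metadata.

    Covariates are differenced over pairs: Z_ij = (A_j - A_i, c_j - c_i, ...).
    For the purely marginal model (``marginal=True``) same-group pairs carry
    a zero score contribution and are skipped; conditional models retain
    them because they inform the covariate coefficients.
    """
    n = rsigns.n_samples
    if len(meta.sample_ids) != n:
        raise PIMError("metadata not aligned with the sign matrix")
    covariate_names = list(covariate_names or [])
    a = meta.group
    cols = [a]
    names = ["A"]
    for name in covariate_names:
        if name == "library_size":
            cols.append(meta.library_size)
        else:
            cols.append(meta.data[name].to_numpy(dtype=float))
        names.append(name)
    V = np.column_stack(cols)  # (n, k) per-sample values
    iu, ju = np.triu_indices(n, 1)
    Z = V[ju] - V[iu]
    I = rsigns.values[iu, ju]
    if marginal:
        keep = Z[:, 0] != 0
        iu, ju, Z, I = iu[keep], ju[keep], Z[keep], I[keep]
    # drop covariate columns that are identically zero over all pairs
    # (constant covariates); the group column must remain informative
    keep_cols = [0] + [k for k in range(1, Z.shape[1]) if np.any(Z[:, k] != 0)]
    Z = Z[:, keep_cols]
    names = [names[k] for k in keep_cols]
    if Z.shape[0] == 0 or not np.any(Z[:, 0] != 0):
        raise PIMError("no informative pairs (single-group data?)")
    return PIMDesign(
        pairs=np.column_stack([iu, ju]),
        pseudo_obs=I.astype(float),
        Z=Z.astype(float),
        n_samples=n,
        names=names,
    )


def _sandwich(design: PIMDesign, beta: np.ndarray) -> np.ndarray:
    Z, I = design.Z, design.pseudo_obs
    p = expit(Z @ beta)
    w = np.maximum(p * (1 - p), 1e-10)
    A = Z.T @ (Z * w[:, None])
    r = I - p
    g = Z * r[:, None]  # (P, k) per-pair score contributions
    # S[s] = sum of g over pairs containing sample s; then
    # sum_s S_s S_s' counts couples sharing exactly one index once and the
    # self couple twice, so subtract the diagonal term once.
    k = Z.shape[1]
    S = np.zeros((design.n_samples, k))
    np.add.at(S, design.pairs[:, 0], g)
    np.add.at(S, design.pairs[:, 1], g)
    B = S.T @ S - g.T @ g
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.full((k, k), np.nan)
    return A_inv @ B @ A_inv.T


def fit_pim(design: PIMDesign) -> PIMFit:
    """Solve the PIM estimating equations by Newton iteration from beta = 0.

    A probabilistic index of exactly 0 or 1 on the informative pairs has no
    finite solution; the estimate is then capped at +/-15 on the logit scale
    and flagged (``degenerate``, ``converged=False``).
    """
    Z, I = design.Z, design.pseudo_obs
    k = Z.shape[1]
    beta = np.zeros(k)
    converged = False
    degenerate = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        p = expit(Z @ beta)
        U = Z.T @ (I - p)
        if np.max(np.abs(U)) < SCORE_TOL:
            converged = True
            break
        w = np.maximum(p * (1 - p), 1e-10)
        A = Z.T @ (Z * w[:, None])
        try:
            step = np.linalg.solve(A, U)
        except np.linalg.LinAlgError:
            degenerate = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > BETA_CAP:
            degenerate = True
            beta = np.clip(beta, -BETA_CAP, BETA_CAP)
            break
    cov = _sandwich(design, beta)
    return PIMFit(
        coefficients=beta,
        covariance=cov,
        converged=converged and not degenerate,
        n_iter=n_iter,
        degenerate=degenerate,
        names=list(design.names),
    )


def pim_wald_test(fit: PIMFit, coef: str = "A") -> tuple[float, float]:
    """Two-sided Wald test of a PIM coefficient from the sandwich SE."""
    if not fit.converged:
        raise PIMError("Wald test on a non-converged PIM fit")
    idx = fit.names.index(coef) if fit.names else 0
    beta = fit.coefficients[idx]
    se = fit.se()[idx]
    if se == 0 or not np.isfinite(se):
        if beta == 0:
            return 0.0, 1.0
        raise PIMError("degenerate sandwich variance")
    z = beta / se
    return float(z), float(2 * norm.sf(abs(z)))
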