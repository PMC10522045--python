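"""Per-taxon differential-abundance tests built on sign transforms.

Six procedures, all testing H0: beta_A = 0 for one taxon against a
reference frame, differing in the sign type and in how the library size L
(and optional covariates X) enter:

==========  =========================================================
s-marg      logistic regression of S-signs on A (marginal odds ratio)
s-cond      logistic regression of S-signs on A, L (+X)
s-ri        regression-imputation (standardised) marginal odds ratio
r-marg      PIM on R-signs with pair covariate A*-A (marginal
            probabilistic index)
r-cond      PIM on R-signs with A*-A, L*-L (+X*-X)
r-ri        regression-imputation marginal probabilistic index
==========  =========================================================

The RI estimators fit the conditional model, then average its predictions
over the empirical covariate distribution, so the estimand keeps the
*marginal* interpretation while covariate information sharpens the
estimate.  Their standard errors come from influence curves: the variance
is the empirical second moment of per-sample influence contributions,
optionally cross-checked by a nonparametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .glm import GLMError, GLMFit, fit_logistic
from .io import CountTable, SampleMetadata
from .pim import PIMError, build_pim_design, fit_pim, pim_wald_test
from .reference import ReferenceFrame, ReferenceFrameError, adjusted_reference
from .signs import r_sign_matrix, s_sign

METHODS = ("s-marg", "s-cond", "s-ri", "r-marg", "r-cond", "r-ri")


class MethodError(ValueError):
    pass


@dataclass
class FitResult:
    taxon_id: str
    method: str
    estimate: float
    se: float
    z: float
    p: float
    effect_size: float
    effect_scale: str  # "odds_ratio" or "prob_index"
    converged: bool
    firth_used: bool = False
    rf_flag: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RIEstimateS:
    """Regression-imputation marginal log-odds-ratio for S-signs."""

    beta_RI: float
    sigma: float
    pi0: float
    pi1: float
    delta: float
    ic: np.ndarray
    firth_used: bool = False
    bootstrap_se: float | None = None


@dataclass
class RIEstimateR:
    """Regression-imputation marginal probabilistic index for R-signs."""

    beta_RI: float
    sigma: float
    delta: float
    ic: np.ndarray
    converged: bool = True
    bootstrap_se: float | None = None


# ---------------------------------------------------------------------------
# effect-size conversions

def or_from_beta(beta: float, ndigits: int | None = 3) -> float:
    """Odds ratio exp(beta), rounded for display (3 decimals by default)."""
    val = float(np.exp(beta))
    return round(val, ndigits) if ndigits is not None else val


def pi_from_beta(beta: float, ndigits: int | None = 3) -> float:
    """Probabilistic index expit(beta), rounded for display."""
    val = float(expit(beta))
    return round(val, ndigits) if ndigits is not None else val


def percent_lower_odds(beta: float) -> float:
    """Percent reduction in odds implied by a negative log-odds-ratio,
    rounded to the integer percent a reader would quote."""
    return float(round(100 * (1 - or_from_beta(beta))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise MethodError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# design helpers

def _s_design(meta: SampleMetadata, covariates: list[str] | None):
    """Intercept + A (+ standardised covariates) design for S-sign fits.

    Covariates are centred/scaled internally for numerical conditioning;
    coefficients are transformed back to the original scale afterwards.
    Zero-variance covariate columns are dropped.
    """
    a = meta.group
    cols = [np.ones_like(a), a]
    names = ["intercept", "A"]
    scales: list[tuple[float, float]] = [(0.0, 1.0), (0.0, 1.0)]
    for name in covariates or []:
        x = (
            meta.library_size
            if name == "library_size"
            else meta.data[name].to_numpy(dtype=float)
        )
        sd = float(np.std(x))
        if sd == 0:
            continue  # constant column carries no information
        mu = float(np.mean(x))
        cols.append((x - mu) / sd)
        names.append(name)
        scales.append((mu, sd))
    return np.column_stack(cols), names, scales


def _unscale(fit: GLMFit, scales) -> GLMFit:
    """Map coefficients/covariance from the standardised to the raw scale."""
    k = len(fit.coefficients)
    T = np.zeros((k, k))
    for j, (mu, sd) in enumerate(scales):
        T[j, j] = 1.0 / sd
        if j >= 1 and mu != 0.0:
            T[0, j] = -mu / sd
    fit.coefficients = T @ fit.coefficients
    fit.covariance = T @ fit.covariance @ T.T
    return fit


def _wald(beta: float, se: float) -> tuple[float, float]:
    if se == 0 or not np.isfinite(se):
        if beta == 0:
            return 0.0, 1.0
        return float(np.sign(beta) * np.inf), 0.0
    z = beta / se
    return float(z), float(2 * norm.sf(abs(z)))


def _s_fit(table, meta, rf, taxon, covariates, firth):
    adj = adjusted_reference(table, rf, taxon)
    y = s_sign(table.counts.loc[taxon].to_numpy(), adj).values
    if np.all(y == y[0]):
        return None, y, adj  # degenerate: no outcome variation
    X, names, scales = _s_design(meta, covariates)
    fit = fit_logistic(y, X, firth=firth, names=names)
    fit = _unscale(fit, scales)
    return fit, y, adj


def _result_from_glm(taxon, method, fit: GLMFit | None) -> FitResult:
    if fit is None:
        return FitResult(
            taxon, method, np.nan, np.nan, 0.0, 1.0, np.nan,
            "odds_ratio", converged=False,
        )
    idx = fit.names.index("A")
    beta = float(fit.coefficients[idx])
    se = float(fit.se()[idx])
    z, p = _wald(beta, se)
    return FitResult(
        taxon, method, beta, se, z, p, or_from_beta(beta, None),
        "odds_ratio", converged=bool(fit.converged), firth_used=fit.firth_used,
    )


# ---------------------------------------------------------------------------
# the six procedures

def test_marginal_s(table, meta, rf, taxon, firth: str = "auto") -> FitResult:
    """Marginal S-sign test: logit P{N <= R | A} = b0 + bA A."""
    fit, _, _ = _s_fit(table, meta, rf, taxon, [], firth)
    return _result_from_glm(taxon, "s-marg", fit)


def test_conditional_s(
    table, meta, rf, taxon, covariates: list[str] | None = None, firth: str = "auto"
) -> FitResult:
    """Conditional S-sign test: adds L (and optional X) as regressors."""
    covs = ["library_size"] + [c for c in (covariates or []) if c != "library_size"]
    fit, _, _ = _s_fit(table, meta, rf, taxon, covs, firth)
    return _result_from_glm(taxon, "s-cond", fit)


def test_marginal_r(table, meta, rf, taxon) -> FitResult:
    """Marginal R-sign test: PIM logit P{N/R <= N*/R*} = bA (A* - A)."""
    rs = r_sign_matrix(table.counts.loc[taxon].to_numpy(), rf.reference, taxon)
    design = build_pim_design(rs, meta, [], marginal=True)
    fit = fit_pim(design)
    beta = float(fit.coefficients[0])
    if fit.degenerate:
        return FitResult(
            taxon, "r-marg", beta, np.nan, np.nan, np.nan,
            pi_from_beta(beta, None), "prob_index", converged=False,
        )
    z, p = pim_wald_test(fit, "A")
    return FitResult(
        taxon, "r-marg", beta, float(fit.se()[0]), z, p,
        pi_from_beta(beta, None), "prob_index", converged=fit.converged,
    )


def test_conditional_r(
    table, meta, rf, taxon, covariates: list[str] | None = None
) -> FitResult:
    """Conditional R-sign test: PIM with pair covariates (A*-A, L*-L, ...)."""
    covs = ["library_size"] + [c for c in (covariates or []) if c != "library_size"]
    rs = r_sign_matrix(table.counts.loc[taxon].to_numpy(), rf.reference, taxon)
    design = build_pim_design(rs, meta, covs, marginal=False)
    fit = fit_pim(design)
    idx = design.names.index("A")
    beta = float(fit.coefficients[idx])
    if fit.degenerate:
        return FitResult(
            taxon, "r-cond", beta, np.nan, np.nan, np.nan,
            pi_from_beta(beta, None), "prob_index", converged=False,
        )
    z, p = pim_wald_test(fit, "A")
    return FitResult(
        taxon, "r-cond", beta, float(fit.se()[idx]), z, p,
        pi_from_beta(beta, None), "prob_index", converged=fit.converged,
    )


def ri_s(
    table,
    meta,
    rf,
    taxon,
    covariates: list[str] | None = None,
    firth: str = "auto",
    bootstrap: int = 0,
    seed: int | None = None,
) -> RIEstimateS:
    """Regression-imputation estimator of the marginal S-sign odds ratio.

    Fits the conditional logistic model with A and L (plus optional X),
    standardises the fitted probabilities over the empirical covariate
    distribution, and forms the marginal log-odds-ratio from the
    standardised probabilities pi(1), pi(0).  The variance is the empirical
    second moment of the influence curve; ``bootstrap > 0`` adds a
    nonparametric bootstrap SE.
    """
    covs = ["library_size"] + [c for c in (covariates or []) if c != "library_size"]
    fit, y, _ = _s_fit(table, meta, rf, taxon, covs, firth)
    if fit is None:
        raise MethodError(f"degenerate S-signs for taxon {taxon!r}")
    a = meta.group
    n = len(a)
    delta = float(np.mean(a))
    if not 0 < delta < 1:
        raise MethodError("both groups must be present")
    # predictions at A=a with covariates at observed values, original scale
    beta = fit.coefficients
    names_fit = fit.names

    def _pred(a_val):
        cols = []
        for name in names_fit:
            if name == "intercept":
                cols.append(np.ones(n))
            elif name == "A":
                cols.append(np.full(n, a_val))
            elif name == "library_size":
                cols.append(meta.library_size)
            else:
                cols.append(meta.data[name].to_numpy(dtype=float))
        return expit(np.column_stack(cols) @ beta)

    p1 = _pred(1.0)
    p0 = _pred(0.0)
    pi1 = float(np.mean(p1))
    pi0 = float(np.mean(p0))
    if not (0 < pi0 < 1 and 0 < pi1 < 1):
        raise MethodError("standardised probability on the boundary")
    beta_ri = float(np.log(pi1 / (1 - pi1)) - np.log(pi0 / (1 - pi0)))
    ic = (1.0 / (pi1 * (1 - pi1))) * (a / delta * (y - p1) + p1 - pi1) - (
        1.0 / (pi0 * (1 - pi0))
    ) * ((1 - a) / (1 - delta) * (y - p0) + p0 - pi0)
    sigma = float(np.sqrt(np.sum(ic**2)) / n)
    boot_se = None
    if bootstrap > 0:
        # the per-sample reference must be recomputed on each resampled table
        boot_se = _bootstrap_se(
            table, meta,
            lambda t, m: ri_s(
                t, m, _refit_rf(t, rf), taxon, covariates, firth
            ).beta_RI,
            bootstrap, seed,
        )
    return RIEstimateS(
        beta_RI=beta_ri, sigma=sigma, pi0=pi0, pi1=pi1, delta=delta, ic=ic,
        firth_used=fit.firth_used, bootstrap_se=boot_se,
    )


def ri_r(
    table,
    meta,
    rf,
    taxon,
    covariates: list[str] | None = None,
    bootstrap: int = 0,
    seed: int | None = None,
) -> RIEstimateR:
    """Regression-imputation estimator of the marginal probabilistic index.

    Fits the conditional PIM (pair covariates A*-A and L*-L, plus optional
    X), then averages its predicted comparison probabilities at A=0 vs A*=1
    over all ordered sample pairs.  The variance comes from the per-sample
    influence curve; its empirical second moment over n^2 gives sigma^2.
    """
    covs = ["library_size"] + [c for c in (covariates or []) if c != "library_size"]
    rs = r_sign_matrix(table.counts.loc[taxon].to_numpy(), rf.reference, taxon)
    design = build_pim_design(rs, meta, covs, marginal=False)
    fit = fit_pim(design)
    if fit.degenerate:
        raise MethodError(f"degenerate PIM fit for taxon {taxon!r}")
    a = meta.group
    n = len(a)
    delta = float(np.mean(a))
    if not 0 < delta < 1:
        raise MethodError("both groups must be present")
    coef = dict(zip(fit.names, fit.coefficients))
    beta_a = coef["A"]
    # eta[i, j] = beta_A + beta_L (L_i - L_j) + ... = linear predictor of
    # phat(L_j, L_i), the predicted P{sample j's rel. abundance <= sample i's
    # | A=0, A*=1} at the observed covariates.
    eta = np.full((n, n), beta_a)
    for name, b in coef.items():
        if name == "A":
            continue
        x = (
            meta.library_size
            if name == "library_size"
            else meta.data[name].to_numpy(dtype=float)
        )
        eta += b * (x[:, None] - x[None, :])
    P = expit(eta)  # P[i, j] = phat(L_j, L_i)
    off = ~np.eye(n, dtype=bool)
    beta_ri = float(P[off].mean())
    I = rs.values
    # influence curve: observed-comparison terms for each arm, centring at
    # -2 beta_ri, and a group-imbalance correction from the predictions
    sum_a_i = (I * a[None, :])[off].reshape(n, n - 1).sum(axis=1)
    term1 = (1 - a) / (1 - delta) * (sum_a_i / (n - 1)) / delta
    sum_na_j = (I.T * (1 - a)[None, :])[off].reshape(n, n - 1).sum(axis=1)
    term2 = a / delta * (sum_na_j / (n - 1)) / (1 - delta)
    corr = (P.T / (1 - delta) - P / delta)[off].reshape(n, n - 1).sum(axis=1)
    term4 = (a - delta) * corr / (n - 1)
    ic = term1 + term2 - 2 * beta_ri + term4
    sigma = float(np.sqrt(np.sum(ic**2)) / n)
    boot_se = None
    if bootstrap > 0:
        boot_se = _bootstrap_se(
            table, meta,
            lambda t, m: ri_r(t, m, _refit_rf(t, rf), taxon, covariates).beta_RI,
            bootstrap, seed,
        )
    return RIEstimateR(
        beta_RI=beta_ri, sigma=sigma, delta=delta, ic=ic, bootstrap_se=boot_se
    )


def _refit_rf(table, rf):
    """Rebuild the per-sample reference for a resampled table (same taxa)."""
    from .reference import user_reference_frame

    return user_reference_frame(table, rf.taxa)


def _bootstrap_se(table, meta, statistic, n_boot: int, seed) -> float:
    """Nonparametric bootstrap over samples (redrawn until both groups
    present); the reference frame is held fixed."""
    rng = np.random.default_rng(seed)
    n = table.n_samples
    sample_ids = np.array(table.sample_ids)
    stats = []
    for _ in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            g = meta.group[idx]
            if 0 < g.mean() < 1:
                break
        new_ids = [f"bs{k}" for k in range(n)]
        boot_counts = table.counts.iloc[:, idx].copy()
        boot_counts.columns = new_ids
        boot_meta_df = meta.data.iloc[idx].copy()
        boot_meta_df.index = new_ids
        bt = CountTable(boot_counts)
        bm = SampleMetadata(boot_meta_df, list(meta.covariates))
        try:
            stats.append(statistic(bt, bm))
        except (MethodError, GLMError, PIMError, ReferenceFrameError):
            continue
    if len(stats) < 2:
        raise MethodError("bootstrap produced too few valid replicates")
    return float(np.std(stats, ddof=1))


def test_ri_s(table, meta, rf, taxon, covariates=None, firth="auto") -> FitResult:
    est = ri_s(table, meta, rf, taxon, covariates, firth)
    z, p = _wald(est.beta_RI, est.sigma)
    return FitResult(
        taxon, "s-ri", est.beta_RI, est.sigma, z, p,
        or_from_beta(est.beta_RI, None), "odds_ratio",
        converged=True, firth_used=est.firth_used,
    )


def test_ri_r(table, meta, rf, taxon, covariates=None) -> FitResult:
    est = ri_r(table, meta, rf, taxon, covariates)
    z, p = _wald(est.beta_RI - 0.5, est.sigma)
    return FitResult(
        taxon, "r-ri", est.beta_RI, est.sigma, z, p,
        est.beta_RI, "prob_index", converged=True,
    )


# ---------------------------------------------------------------------------
# driver

_DISPATCH = {
    "s-marg": lambda t, m, rf, tax, cov, firth: test_marginal_s(t, m, rf, tax, firth),
    "s-cond": lambda t, m, rf, tax, cov, firth: test_conditional_s(t, m, rf, tax, cov, firth),
    "s-ri": lambda t, m, rf, tax, cov, firth: test_ri_s(t, m, rf, tax, cov, firth),
    "r-marg": lambda t, m, rf, tax, cov, firth: test_marginal_r(t, m, rf, tax),
    "r-cond": lambda t, m, rf, tax, cov, firth: test_conditional_r(t, m, rf, tax, cov),
    "r-ri": lambda t, m, rf, tax, cov, firth: test_ri_r(t, m, rf, tax, cov),
}


def run_all_taxa(
    table: CountTable,
    meta: SampleMetadata,
    rf: ReferenceFrame,
    method: str,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    firth: str = "auto",
    seed: int | None = None,
    include_rf: bool = False,
) -> pd.DataFrame:
    """Apply one procedure to every testable taxon and BH-adjust within the run.

    Reference-frame taxa are excluded by default (a taxon should not be
    tested against a reference that contains it); failed fits are kept as
    rows with NA p-values and are excluded from the BH family.  Rows are
    sorted by adjusted p then taxon id, deterministically.
    """
    if method not in METHODS:
        raise MethodError(f"unknown method {method!r}; choose from {METHODS}")
    meta = meta.aligned_to(table.sample_ids)
    rf_set = set(rf.taxa)
    taxa = [t for t in table.taxon_ids if include_rf or t not in rf_set]
    if not taxa:
        raise MethodError("no taxa left to test outside the reference frame")
    rows = []
    fn = _DISPATCH[method]
    for taxon in taxa:
        try:
            res = fn(table, meta, rf, taxon, covariates, firth)
        except (MethodError, GLMError, PIMError, ReferenceFrameError, np.linalg.LinAlgError):
            res = FitResult(
                taxon, method, np.nan, np.nan, np.nan, np.nan, np.nan,
                "odds_ratio" if method.startswith("s") else "prob_index",
                converged=False,
            )
        res.rf_flag = taxon in rf_set
        rows.append(res.as_dict())
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        df.loc[ok, "p_adj"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    df["discovery"] = df["p_adj"] <= alpha
    df = df.sort_values(["p_adj", "taxon_id"], na_position="last").reset_index(drop=True)
    cols = [
        "taxon_id", "method", "estimate", "se", "z", "p", "p_adj",
        "effect_size", "effect_scale", "converged", "firth_used", "rf_flag",
        "discovery",
    ]
    return df[cols]
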