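import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from signda import (
    PIMError,
    SampleMetadata,
    build_pim_design,
    fit_pim,
    pim_wald_test,
    r_sign_matrix,
)


def _meta(groups, libs=None, **covs):
    n = len(groups)
    data = {"group": groups, "library_size": libs if libs is not None else np.ones(n)}
    data.update(covs)
    return SampleMetadata(pd.DataFrame(data, index=[f"s{i}" for i in range(n)]))


def _marginal_fit(values, groups):
    rs = r_sign_matrix(np.asarray(values), np.ones(len(values)), "t")
    design = build_pim_design(rs, _meta(groups), [], marginal=True)
    return fit_pim(design), design


def brute_force_mw(values, groups):
    """Mann-Whitney proportion: mean tie-aware indicator over g0 x g1 pairs."""
    v = np.asarray(values, dtype=float)
    g0 = v[np.asarray(groups) == 0]
    g1 = v[np.asarray(groups) == 1]
    total = 0.0
    for a in g0:
        for b in g1:
            total += 1.0 if a < b else (0.5 if a == b else 0.0)
    return total / (len(g0) * len(g1))


class TestDesign:
    def test_pair_count(self):
        rs = r_sign_matrix(np.array([1, 2, 3, 4]), np.ones(4), "t")
        design = build_pim_design(rs, _meta([0, 0, 1, 1]), [])
        assert design.Z.shape[0] == 6  # C(4, 2)

    def test_same_group_pairs_have_zero_group_covariate(self):
        rs = r_sign_matrix(np.array([1, 2, 3, 4]), np.ones(4), "t")
        design = build_pim_design(rs, _meta([0, 0, 1, 1]), [])
        within = (design.pairs < 2).all(axis=1) | (design.pairs >= 2).all(axis=1)
        assert np.all(design.Z[within, 0] == 0)

    def test_conditional_pair_covariates_by_differencing(self):
        rs = r_sign_matrix(np.array([1, 2]), np.ones(2), "t")
        design = build_pim_design(
            rs, _meta([0, 1], libs=[100.0, 250.0]), ["library_size"]
        )
        assert design.Z.tolist() == [[1.0, 150.0]]

    def test_single_group_errors(self):
        rs = r_sign_matrix(np.array([1, 2, 3]), np.ones(3), "t")
        with pytest.raises(Exception):
            build_pim_design(rs, _meta([0, 0, 0]), [], marginal=True)


class TestMarginalFit:
    def test_worked_toy_example(self):
        # g0 = (1,2,3), g1 = (2,4,5): mean between-group indicator 7.5/9
        fit, _ = _marginal_fit([1, 2, 3, 2, 4, 5], [0, 0, 0, 1, 1, 1])
        assert expit(fit.coefficients[0]) == pytest.approx(7.5 / 9, abs=1e-8)
        assert fit.coefficients[0] == pytest.approx(np.log(7.5 / 1.5), abs=1e-7)

    def test_identical_groups_zero_effect(self):
        fit, _ = _marginal_fit([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_mann_whitney_oracle_on_random_data(self):
        """The marginal PIM estimate is exactly the MW proportion."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            n0, n1 = rng.integers(3, 8, 2)
            vals = rng.integers(0, 6, n0 + n1)
            groups = [0] * n0 + [1] * n1
            mw = brute_force_mw(vals, groups)
            if mw in (0.0, 1.0):
                continue
            fit, _ = _marginal_fit(vals, groups)
            assert expit(fit.coefficients[0]) == pytest.approx(mw, abs=1e-7)

    def test_degenerate_pi_capped_and_flagged(self):
        fit, _ = _marginal_fit([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert fit.degenerate and not fit.converged
        assert abs(fit.coefficients[0]) == pytest.approx(15.0)

    def test_orientation_invariance(self):
        """Flipping stored pair orientation leaves the fit unchanged."""
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 10, 10)
        rs = r_sign_matrix(vals, np.ones(10), "t")
        design = build_pim_design(rs, _meta([0, 1] * 5), [], marginal=True)
        base = fit_pim(design).coefficients[0]
        flip = rng.random(design.Z.shape[0]) < 0.5
        design.pseudo_obs[flip] = 1 - design.pseudo_obs[flip]
        design.Z[flip] = -design.Z[flip]
        design.pairs[flip] = design.pairs[flip][:, ::-1]
        assert fit_pim(design).coefficients[0] == pytest.approx(base, abs=1e-8)


class TestWaldInference:
    def test_zero_estimate_p_one(self):
        fit, _ = _marginal_fit([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        z, p = pim_wald_test(fit, "A")
        assert z == pytest.approx(0.0, abs=1e-6) and p == pytest.approx(1.0, abs=1e-6)

    def test_z_to_p_normal_tail(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 1, 20)])
        rs = r_sign_matrix(vals, np.ones(40), "t")
        design = build_pim_design(rs, _meta([0] * 20 + [1] * 20), [], marginal=True)
        fit = fit_pim(design)
        z, p = pim_wald_test(fit, "A")
        from scipy.stats import norm

        assert p == pytest.approx(2 * norm.sf(abs(z)), abs=1e-12)

    def test_non_converged_fit_rejected(self):
        fit, _ = _marginal_fit([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        with pytest.raises(PIMError):
            pim_wald_test(fit, "A")

    def test_null_pvalues_approximately_uniform(self):
        """Sandwich-based Wald p-values are near-uniform under the null."""
        from scipy.stats import kstest

        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(400):
            vals = rng.normal(size=40)
            rs = r_sign_matrix(vals, np.ones(40), "t")
            design = build_pim_design(
                rs, _meta([0] * 20 + [1] * 20), [], marginal=True
            )
            fit = fit_pim(design)
            pvals.append(pim_wald_test(fit, "A")[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_sandwich_close_to_mw_analytic_variance(self):
        """On tie-free null data the sandwich SE tracks the analytic variance
        of the Mann-Whitney proportion: with p = 1/2 and both Q terms 1/3,
        Var(p_hat) = [p(1-p) + (n0+n1-2)(1/3 - p^2)] / (n0 n1)."""
        rng = np.random.default_rng(5)
        n0 = n1 = 50
        analytic = (0.25 + (n0 + n1 - 2) * (1 / 3 - 0.25)) / (n0 * n1)
        meta = _meta([0] * n0 + [1] * n1)
        reps, sand = [], []
        for _ in range(400):
            vals = rng.normal(size=n0 + n1)
            rs = r_sign_matrix(vals, np.ones(n0 + n1), "t")
            design = build_pim_design(rs, meta, [], marginal=True)
            fit = fit_pim(design)
            mw = float(np.mean(vals[:n0, None] < vals[None, n0:]))
            reps.append(mw)
            # delta method: Var(expit(b)) = (mw(1-mw))^2 Var(b)
            sand.append((mw * (1 - mw)) ** 2 * fit.covariance[0, 0])
        assert np.mean(sand) == pytest.approx(analytic, rel=0.10)
        # and the Monte-Carlo spread is consistent with the same formula
        assert np.var(reps, ddof=1) == pytest.approx(analytic, rel=0.20)
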