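import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from signda import (
    CountTable,
    MethodError,
    SampleMetadata,
    bh_adjust,
    or_from_beta,
    percent_lower_odds,
    pi_from_beta,
    ri_r,
    ri_s,
    run_all_taxa,
    user_reference_frame,
)
# aliased so pytest does not collect the library's test_* entry points
from signda import test_conditional_r as conditional_r
from signda import test_conditional_s as conditional_s
from signda import test_marginal_r as marginal_r
from signda import test_marginal_s as marginal_s


class TestEffectConversions:
    @pytest.mark.parametrize(
        "beta,printed,tol", [(-3.135, 0.044, 1e-3), (-2.841, 0.058, 5e-4), (0.0, 1.0, 1e-12)]
    )
    def test_odds_ratio_display(self, beta, printed, tol):
        # the log-odds inputs are themselves printed to 3 decimals, so two
        # display roundings compose: agreement to one unit in the last place
        assert or_from_beta(beta, None) == pytest.approx(printed, abs=tol)

    @pytest.mark.parametrize(
        "beta,ndigits,expected", [(0.511, 3, 0.625), (0.433, 2, 0.61), (0.0, 3, 0.5)]
    )
    def test_probabilistic_index_display(self, beta, ndigits, expected):
        assert pi_from_beta(beta, ndigits) == pytest.approx(expected, abs=5e-4)

    def test_percent_lower_odds(self):
        assert percent_lower_odds(-3.135) == 96.0


class TestBHAdjust:
    def test_step_up_definition(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0] * 3

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(MethodError):
            bh_adjust([0.5, 1.5])


class TestEqualityReductions:
    """With a constant library size, conditioning on L is vacuous: the
    conditional and RI estimators must collapse onto the marginal ones."""

    def test_s_family(self, constant_library_dataset):
        table, meta, rf = constant_library_dataset
        marg = marginal_s(table, meta, rf, "t5")
        cond = conditional_s(table, meta, rf, "t5")
        est = ri_s(table, meta, rf, "t5")
        assert cond.estimate == pytest.approx(marg.estimate, abs=1e-7)
        assert est.beta_RI == pytest.approx(marg.estimate, abs=1e-7)

    def test_r_family(self, constant_library_dataset):
        table, meta, rf = constant_library_dataset
        marg = marginal_r(table, meta, rf, "t5")
        cond = conditional_r(table, meta, rf, "t5")
        est = ri_r(table, meta, rf, "t5")
        assert cond.estimate == pytest.approx(marg.estimate, abs=1e-7)
        assert est.beta_RI == pytest.approx(expit(marg.estimate), abs=1e-7)


class TestRIEstimators:
    def test_ri_s_influence_mean_zero(self, small_dataset):
        table, meta, rf = small_dataset
        est = ri_s(table, meta, rf, "t5")
        assert abs(est.ic.mean()) < 1e-6
        assert 0 < est.pi0 < 1 and 0 < est.pi1 < 1

    def test_ri_r_estimate_in_unit_interval(self, small_dataset):
        table, meta, rf = small_dataset
        est = ri_r(table, meta, rf, "t5")
        assert 0 <= est.beta_RI <= 1

    def test_identical_groups_give_null_values(self):
        counts = pd.DataFrame(
            np.tile(np.arange(1, 11), (6, 1)),
            index=[f"t{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(10)],
        )
        # both groups see the same multiset of relative abundances
        table = CountTable(counts)
        meta = SampleMetadata(
            pd.DataFrame(
                {"group": [0, 1] * 5, "library_size": np.full(10, 100.0)},
                index=counts.columns,
            )
        )
        rf = user_reference_frame(table, ["t0"])
        est = ri_r(table, meta, rf, "t3")
        assert est.beta_RI == pytest.approx(0.5, abs=1e-7)

    @pytest.mark.parametrize("kind", ["s", "r"])
    def test_ic_se_vs_bootstrap(self, kind):
        """Analytic influence-curve SEs track the bootstrap at n=100."""
        rng = np.random.default_rng(21)
        n = 100
        lib = rng.integers(800, 4000, n).astype(float)
        base = np.maximum(rng.poisson(lib / 50.0), 1)
        counts = pd.DataFrame(
            {
                f"s{i}": [
                    base[i],
                    max(1, int(base[i] * 0.9)),
                    max(1, int(base[i] * 1.1)),
                    rng.poisson(lib[i] / 100.0),
                    rng.poisson(lib[i] / 80.0),
                ]
                for i in range(n)
            },
            index=["r0", "r1", "r2", "x0", "x1"],
        )
        table = CountTable(counts)
        meta = SampleMetadata(
            pd.DataFrame(
                {"group": [0] * 50 + [1] * 50, "library_size": lib},
                index=counts.columns,
            )
        )
        rf = user_reference_frame(table, ["r0", "r1", "r2"])
        if kind == "s":
            est = ri_s(table, meta, rf, "x0", bootstrap=300, seed=7)
        else:
            est = ri_r(table, meta, rf, "x0", bootstrap=300, seed=7)
        assert est.bootstrap_se == pytest.approx(est.sigma, rel=0.15)


class TestDegenerateAndSeparated:
    def test_constant_s_signs_give_p_one(self):
        # target counts far below the adjusted reference in every sample
        counts = pd.DataFrame(
            {
                f"s{i}": [100, 100, 100, 0] for i in range(10)
            },
            index=["r0", "r1", "r2", "x"],
        )
        counts.loc["x"] = [0] * 10
        table = CountTable(counts)
        meta = SampleMetadata(
            pd.DataFrame(
                {"group": [0] * 5 + [1] * 5, "library_size": np.full(10, 300.0)},
                index=counts.columns,
            )
        )
        rf = user_reference_frame(table, ["r0", "r1", "r2"])
        res = marginal_s(table, meta, rf, "x")
        assert res.p == 1.0 and not res.converged

    def test_separating_group_triggers_firth(self):
        # group 1 counts all above, group 0 all below the adjusted reference
        counts = pd.DataFrame(
            np.vstack(
                [
                    np.full((3, 12), 50),
                    np.array([[2] * 6 + [400] * 6]),
                ]
            ),
            index=["r0", "r1", "r2", "x"],
            columns=[f"s{i}" for i in range(12)],
        )
        table = CountTable(counts)
        meta = SampleMetadata(
            pd.DataFrame(
                {"group": [0] * 6 + [1] * 6, "library_size": np.full(12, 600.0)},
                index=counts.columns,
            )
        )
        rf = user_reference_frame(table, ["r0", "r1", "r2"])
        res = marginal_s(table, meta, rf, "x")
        assert res.firth_used and np.isfinite(res.estimate)
        assert res.p < 0.05


class TestRunAllTaxa:
    def test_rf_taxa_excluded_and_rows_complete(self, small_dataset):
        table, meta, rf = small_dataset
        res = run_all_taxa(table, meta, rf, "r-marg")
        assert len(res) == table.n_taxa - len(rf.taxa)
        assert not set(res["taxon_id"]) & set(rf.taxa)

    def test_deterministic_ordering(self, small_dataset):
        table, meta, rf = small_dataset
        a = run_all_taxa(table, meta, rf, "s-marg", seed=3)
        b = run_all_taxa(table, meta, rf, "s-marg", seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_p_adj_dominates_p(self, small_dataset):
        table, meta, rf = small_dataset
        for method in ("s-marg", "r-marg", "s-ri", "r-ri"):
            res = run_all_taxa(table, meta, rf, method)
            ok = res["p"].notna()
            assert np.all(res.loc[ok, "p_adj"] >= res.loc[ok, "p"] - 1e-12)

    def test_taxon_permutation_invariance(self, small_dataset):
        """Method-level compositional coherence: permuting taxon order and
        deleting an untested non-RF taxon change no test result."""
        table, meta, rf = small_dataset
        base = run_all_taxa(table, meta, rf, "r-marg").set_index("taxon_id")
        shuffled = CountTable(table.counts.iloc[::-1])
        perm = run_all_taxa(shuffled, meta, rf, "r-marg").set_index("taxon_id")
        np.testing.assert_allclose(
            base["p"].sort_index(), perm["p"].sort_index(), atol=1e-12
        )
        reduced = CountTable(table.counts.drop(index="t11"))
        sub = run_all_taxa(reduced, meta, rf, "r-marg").set_index("taxon_id")
        np.testing.assert_allclose(
            base["estimate"].drop("t11").sort_index(),
            sub["estimate"].sort_index(),
            atol=1e-12,
        )

    def test_unknown_method_rejected(self, small_dataset):
        table, meta, rf = small_dataset
        with pytest.raises(MethodError, match="unknown method"):
            run_all_taxa(table, meta, rf, "t-test")
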