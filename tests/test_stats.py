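"""Group comparison, FDR, partial rank correlation, stepwise regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mstates.errors import InvalidArgumentError
from mstates.stats import (
    chi_square_2x2,
    compare_groups,
    fdr_bh,
    partial_rank_correlation,
    stepwise_regression,
)


class TestChiSquare:
    def test_published_sex_by_group_table(self):
        chi2, p, df = chi_square_2x2([[25, 31], [14, 24]])
        assert chi2 == pytest.approx(0.567, abs=5e-4)
        assert p == pytest.approx(0.451, abs=5e-4)
        assert df == 1

    def test_proportional_table_gives_zero(self):
        chi2, _, _ = chi_square_2x2([[10, 10], [20, 20]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association(self):
        chi2, _, _ = chi_square_2x2([[5, 0], [0, 5]])
        assert chi2 == pytest.approx(10.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidArgumentError):
            chi_square_2x2([[5, 0], [5, 0]])


class TestFdrBh:
    def test_hand_applied_benjamini_hochberg(self):
        out = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.123])[0] == pytest.approx(0.123)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw_and_capped(self, pvals):
        out = fdr_bh(pvals)
        assert np.all(out >= np.asarray(pvals) - 1e-12)
        assert np.all(out <= 1.0 + 1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_order_invariant_and_rank_preserving(self, pvals, rnd):
        out = fdr_bh(pvals)
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        out_perm = fdr_bh([pvals[i] for i in perm])
        assert np.allclose(sorted(out), sorted(out_perm), atol=1e-12)
        # step-up with cumulative minimum never swaps the order of two p-values
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestCompareGroups:
    def _table(self, x, y, name="v"):
        return pd.DataFrame({
            "group": ["AD"] * len(x) + ["HC"] * len(y),
            name: np.concatenate([x, y]),
        })

    def test_normal_data_uses_t_test(self):
        rng = np.random.default_rng(0)
        df = self._table(rng.normal(0, 1, 30), rng.normal(0.2, 1, 30))
        out = compare_groups(df)
        assert out.loc[0, "test"] == "t"
        x, y = df[df.group == "AD"].v, df[df.group == "HC"].v
        assert out.loc[0, "p_raw"] == pytest.approx(
            sps.ttest_ind(x, y, equal_var=True).pvalue)

    def test_skewed_data_uses_mann_whitney_z(self):
        rng = np.random.default_rng(1)
        df = self._table(rng.exponential(1, 40) ** 2, rng.exponential(1.5, 40) ** 2)
        out = compare_groups(df)
        assert out.loc[0, "test"] == "mannwhitney_z"
        # z and the asymptotic two-sided p must agree
        z = out.loc[0, "statistic"]
        assert out.loc[0, "p_raw"] == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_single_variable_family_adjusted_equals_raw(self):
        rng = np.random.default_rng(2)
        df = self._table(rng.normal(size=12), rng.normal(size=12))
        out = compare_groups(df, families={"solo": ["v"]})
        assert out.loc[0, "p_fdr"] == pytest.approx(out.loc[0, "p_raw"])

    def test_families_partition_the_correction(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "group": ["AD"] * 15 + ["HC"] * 15,
            "a1": rng.normal(size=30), "a2": rng.normal(size=30),
            "b1": rng.normal(size=30),
        })
        out = compare_groups(df, families={"fam_a": ["a1", "a2"], "fam_b": ["b1"]})
        b1 = out[out.variable == "b1"].iloc[0]
        assert b1.p_fdr == pytest.approx(b1.p_raw)

    def test_constant_variable_skipped_with_warning(self):
        df = self._table(np.zeros(10), np.zeros(10))
        with pytest.warns(UserWarning):
            out = compare_groups(df)
        assert len(out) == 0


class TestPartialRankCorrelation:
    def test_perfect_monotone_relation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        cov = rng.normal(size=(50, 2))
        r = partial_rank_correlation(x, x.copy(), cov)
        assert r.rho == pytest.approx(1.0)

    def test_null_at_large_n(self):
        rng = np.random.default_rng(1)
        r = partial_rank_correlation(rng.normal(size=1000),
                                     rng.normal(size=1000),
                                     rng.normal(size=(1000, 3)))
        assert abs(r.rho) < 0.08

    def test_no_covariates_equals_spearman(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r = partial_rank_correlation(x, y)
        rho_sp, p_sp = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(rho_sp, abs=1e-9)

    def test_matches_pingouin_on_ranked_covariates(self):
        # pingouin ranks covariates too; feeding it pre-ranked covariates
        # makes the two estimators coincide
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n = 60
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = -z + rng.normal(size=n)
        cov = sps.rankdata(z)
        ours = partial_rank_correlation(x, y, cov)
        df = pd.DataFrame({"x": sps.rankdata(x), "y": sps.rankdata(y), "z": cov})
        theirs = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                       method="pearson")
        assert ours.rho == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-9)
        assert ours.p == pytest.approx(float(theirs["p_val"].iloc[0]), abs=1e-9)

    def test_insufficient_n_rejected(self):
        with pytest.raises(InvalidArgumentError):
            partial_rank_correlation(np.arange(4.0), np.arange(4.0),
                                     np.ones((4, 2)))


class TestStepwiseRegression:
    def test_recovers_known_support(self):
        rng = np.random.default_rng(0)
        n = 80
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(1, 6)})
        y = 2.0 * X["x1"].to_numpy() + 0.05 * rng.normal(size=n)
        res = stepwise_regression(y, X)
        assert res.selected == ["x1"]
        assert res.table.loc[0, "coef"] == pytest.approx(2.0, abs=0.05)
        lo, hi = res.table.loc[0, "ci_low"], res.table.loc[0, "ci_high"]
        assert lo <= res.table.loc[0, "coef"] <= hi

    def test_collinear_duplicate_never_enters(self):
        rng = np.random.default_rng(1)
        n = 60
        x1 = rng.normal(size=n)
        X = pd.DataFrame({"x1": x1, "dup": x1.copy(),
                          "x2": rng.normal(size=n)})
        y = x1 + 0.1 * rng.normal(size=n)
        res = stepwise_regression(y, X)
        assert "x1" in res.selected or "dup" in res.selected
        assert not ({"x1", "dup"} <= set(res.selected))

    def test_pure_noise_often_selects_nothing(self):
        rng = np.random.default_rng(2)
        empty = 0
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
            res = stepwise_regression(rng.normal(size=40), X)
            empty += not res.selected
        # ~0.05 entry rate per candidate: most replicates stay empty
        assert empty >= 12

    def test_trace_replays_to_final_model(self):
        rng = np.random.default_rng(3)
        n = 70
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(4)})
        y = X["x0"] + 0.5 * X["x2"] + 0.2 * rng.normal(size=n)
        res = stepwise_regression(y, X)
        replay: list[str] = []
        for action, var, _p in res.trace:
            if action == "add":
                replay.append(var)
            else:
                replay.remove(var)
        assert replay == res.selected
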