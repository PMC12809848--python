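"""Summary tests, ANCOVA, post hoc, effect sizes, TFCE and permutation inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from dmnflow import stats as st


def make_raw(mean, sd, n, rng):
    """Raw sample with exactly the requested mean and (ddof=1) SD."""
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestTFromSummary:
    def test_equal_means_zero(self):
        assert st.t_from_summary(5, 1, 10, 5, 1, 10).statistic == pytest.approx(0.0)

    def test_matches_raw_data_oracle(self, rng):
        a = make_raw(3.0, 1.5, 20, rng)
        b = make_raw(4.2, 2.0, 15, rng)
        got = st.t_from_summary(a.mean(), a.std(ddof=1), 20, b.mean(), b.std(ddof=1), 15)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
        assert got.statistic == pytest.approx(t_ref)
        assert got.p_value == pytest.approx(p_ref)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.t_from_summary(1, 0.0, 10, 2, 1, 10)
        with pytest.raises(ValueError):
            st.t_from_summary(1, 1, 1, 2, 1, 10)


class TestAnovaFromSummary:
    def test_identical_means_zero(self):
        res = st.anova_from_summary([(5, 1, 10), (5, 2, 12), (5, 1.5, 8)])
        assert res.statistic == pytest.approx(0.0)

    def test_matches_raw_data_oracle(self, rng):
        groups = [make_raw(m, s, n, rng)
                  for m, s, n in [(1.0, 1.0, 12), (1.5, 1.2, 15), (0.7, 0.9, 10)]]
        res = st.anova_from_summary(
            [(g.mean(), g.std(ddof=1), len(g)) for g in groups]
        )
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)


class TestChiSquare:
    def test_proportional_table_zero(self):
        res = st.chi_square_counts([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_2x2(self):
        # [[10,20],[20,10]]: expected all 15, chi2 = 4 * 25/15 = 20/3
        res = st.chi_square_counts([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == (1,)

    def test_matches_hand_formula_on_random_tables(self, rng):
        for _ in range(10):
            tab = rng.integers(1, 40, (3, 4)).astype(float)
            res = st.chi_square_counts(tab)
            expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            chi2 = ((tab - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(chi2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            st.chi_square_counts([[0, 0], [3, 4]])


class TestAncova:
    def _data(self, rng, n=60, effect=0.0):
        group = np.repeat(["HC", "nonTRS", "TRS"], n // 3)
        cov = rng.standard_normal((n, 2))
        y = rng.standard_normal(n) + 0.5 * cov[:, 0]
        y[group == "TRS"] += effect
        return y, group, cov

    def test_constant_covariates_reduce_to_oneway_anova(self, rng):
        y, group, _ = self._data(rng)
        fit = st.ancova_f(y, group, None)
        f_ref, p_ref = sps.f_oneway(*(y[group == g] for g in ("HC", "nonTRS", "TRS")))
        assert fit.result.statistic == pytest.approx(f_ref)
        assert fit.result.p_value == pytest.approx(p_ref)

    def test_matches_statsmodels_partial_f(self, rng):
        import statsmodels.api as sm

        y, group, cov = self._data(rng, effect=0.5)
        fit = st.ancova_f(y, group, cov)
        dummies = np.column_stack([(group == "nonTRS"), (group == "TRS")]).astype(float)
        X_full = sm.add_constant(np.hstack([dummies, cov]))
        X_red = sm.add_constant(cov)
        full = sm.OLS(y, X_full).fit()
        red = sm.OLS(y, X_red).fit()
        f_ref, p_ref, _ = full.compare_f_test(red)
        assert fit.result.statistic == pytest.approx(f_ref)
        assert fit.result.p_value == pytest.approx(p_ref)
        assert fit.result.df == (2, len(y) - 3 - 2)

    def test_power_matches_noncentral_f_oracle(self):
        """Planted 0.6-SD shift in one of three groups, n=30/group: the
        simulated rejection rate matches the closed-form noncentral-F power."""
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng([s, 41])
            y, group, cov = self._data(rng, n=90, effect=0.6)
            fit = st.ancova_f(y, group, cov)
            hits += fit.result.p_value < 0.05
        # group deviations (-0.2, -0.2, +0.4) around the grand mean
        lam = 30 * (0.2**2 + 0.2**2 + 0.4**2)
        df1, df2 = 2, 90 - 3 - 2
        fcrit = sps.f.isf(0.05, df1, df2)
        power = sps.ncf.sf(fcrit, df1, df2, lam)
        assert hits / n_sim == pytest.approx(power, abs=0.08)
        assert hits / n_sim > 0.5

    def test_collinear_design_rejected(self, rng):
        y, group, cov = self._data(rng)
        cov2 = np.hstack([cov, cov[:, :1]])
        with pytest.raises(ValueError, match="collinear|rank"):
            st.ancova_f(y, group, cov2)


class TestPosthoc:
    def test_equal_groups_high_p(self, rng):
        y = np.tile(rng.standard_normal(30), 2)
        group = np.repeat(["a", "b"], 30)
        fit = st.ancova_f(y, group, None)
        post = st.posthoc_pairwise(fit, "tukey")
        assert post.p_adj.iloc[0] > 0.95

    def test_lsd_no_larger_than_tukey(self, rng):
        y = rng.standard_normal(60)
        group = np.repeat(["a", "b", "c"], 20)
        y[group == "b"] += 0.5
        fit = st.ancova_f(y, group, rng.standard_normal((60, 2)))
        tukey = st.posthoc_pairwise(fit, "tukey")
        lsd = st.posthoc_pairwise(fit, "lsd")
        assert (lsd.p_adj.to_numpy() <= tukey.p_adj.to_numpy() + 1e-12).all()

    def test_matches_statsmodels_tukeyhsd_without_covariates(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        y = rng.standard_normal(75)
        group = np.repeat(["a", "b", "c"], 25)
        y[group == "c"] += 0.8
        fit = st.ancova_f(y, group, None)
        post = st.posthoc_pairwise(fit, "tukey").sort_values(["group1", "group2"])
        ref = pairwise_tukeyhsd(y, group)
        np.testing.assert_allclose(post.p_adj.to_numpy(), ref.pvalues, atol=1e-6)


class TestCohensD:
    def test_zero_f_gives_zero(self):
        assert st.cohens_d_from_f(0.0, 2, 100) == 0.0

    @pytest.mark.parametrize(
        "F,expected", [(3.971, 0.42), (3.409, 0.39)]
    )
    def test_eta_squared_convention(self, F, expected):
        assert round(st.cohens_d_from_f(F, 2, 181), 2) == expected


def tfce_oracle(stat_map, mask, H, E, dh):
    """Brute-force per-threshold labeling with hand-rolled 26-connected BFS."""
    sm = np.where(mask, stat_map, 0.0)
    out = np.zeros_like(sm)
    vmax = sm.max()
    if vmax <= 0:
        return out
    h = dh
    shape = sm.shape
    neigh = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
             if (i, j, k) != (0, 0, 0)]
    while h <= vmax + 1e-12:
        bw = sm >= h
        seen = np.zeros(shape, dtype=bool)
        for start in zip(*np.nonzero(bw)):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.append(v)
                for d in neigh:
                    w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                    if all(0 <= w[i] < shape[i] for i in range(3)) and bw[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
            contrib = len(comp) ** E * h**H * dh
            for v in comp:
                out[v] += contrib
        h += dh
    return out


class TestTFCE:
    def test_zero_map_unchanged(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        out = st.tfce_enhance(np.zeros((5, 5, 5)), mask)
        np.testing.assert_array_equal(out, 0.0)

    def test_single_voxel_closed_form(self):
        """Isolated unit-height voxel, dh=0.1, H=2, E=0.5:
        sum over h in {0.1..1.0} of 1^0.5 * h^2 * 0.1 = 0.385."""
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 1.0
        mask = np.ones((5, 5, 5), dtype=bool)
        out = st.tfce_enhance(stat, mask, H=2.0, E=0.5, dh=0.1)
        expect = sum((0.1 * j) ** 2 * 0.1 for j in range(1, 11))
        assert out[2, 2, 2] == pytest.approx(expect)
        assert out.sum() == pytest.approx(expect)

    def test_matches_labeling_oracle_on_random_map(self, rng):
        stat = np.clip(rng.standard_normal((8, 8, 8)), 0, None)
        mask = rng.random((8, 8, 8)) > 0.2
        got = st.tfce_enhance(stat, mask, H=2.0, E=0.5, n_steps=20)
        dh = (stat * mask).max() / 20
        expect = tfce_oracle(stat, mask, 2.0, 0.5, dh)
        np.testing.assert_allclose(got, expect, atol=1e-10)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=hst.integers(0, 1000))
    def test_monotone_in_input(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.ones((6, 6, 6), dtype=bool)
        a = np.clip(rng.standard_normal((6, 6, 6)), 0, None)
        b = a + rng.random((6, 6, 6))
        dh = b.max() / 30  # common step so enhanced maps are comparable
        ea = st.tfce_enhance(a, mask, dh=dh)
        eb = st.tfce_enhance(b, mask, dh=dh)
        assert (eb - ea >= -1e-10).all()


class TestPermutationFWE:
    def _cohort(self, rng, effect=0.0):
        shape = (6, 6, 6)
        mask = np.ones(shape, dtype=bool)
        N = 30
        group = np.repeat(["HC", "nonTRS", "TRS"], 10)
        cov = rng.standard_normal((N, 2))
        Y = rng.standard_normal((N, mask.sum()))
        if effect:
            blob = np.zeros(shape)
            blob[1:4, 1:4, 1:4] = 1.0
            Y[group == "TRS"] += effect * blob[mask]
        return Y, group, cov, mask

    def test_planted_blob_survives_background_does_not(self, rng):
        Y, group, cov, mask = self._cohort(rng, effect=3.0)
        res = st.permutation_fwe(Y, group, cov, mask, n_perm=200, seed=0,
                                 min_cluster=5)
        sig = res.cluster_labels > 0
        blob = np.zeros(mask.shape, dtype=bool)
        blob[1:4, 1:4, 1:4] = True
        assert (sig & blob).sum() >= 0.5 * blob.sum()
        assert (sig & ~blob).sum() <= 5

    def test_min_cluster_filters_small_clusters(self, rng):
        Y, group, cov, mask = self._cohort(rng, effect=3.0)
        res_all = st.permutation_fwe(Y, group, cov, mask, n_perm=150, seed=0,
                                     min_cluster=1)
        biggest = max(res_all.cluster_sizes.values())
        res_strict = st.permutation_fwe(Y, group, cov, mask, n_perm=150, seed=0,
                                        min_cluster=biggest + 1)
        assert res_strict.cluster_sizes == {}

    def test_requires_enough_permutations(self, rng):
        Y, group, cov, mask = self._cohort(rng)
        with pytest.raises(ValueError, match="n_perm"):
            st.permutation_fwe(Y, group, cov, mask, n_perm=50, seed=0)


class TestSymptomRegression:
    def test_recovers_planted_slope(self, rng):
        n = 120
        x = rng.normal(10, 0.3, n)
        cov = rng.standard_normal((n, 3))
        y = 4.241 * x + cov @ [1.0, -0.5, 0.2] + rng.normal(0, 0.5, n)
        res = st.regress_symptoms(y, x, cov)
        lo, hi = res.ci95
        assert lo < 4.241 < hi
        assert res.statistic == pytest.approx(4.241, abs=0.5)

    def test_duplicated_predictor_rejected(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="collinear"):
            st.regress_symptoms(y, x, x[:, None])
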