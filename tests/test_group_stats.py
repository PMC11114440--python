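import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plihub.group_stats import (
    AnovaResult,
    GatingError,
    bh_fdr,
    fdr_across_bands,
    gg_epsilon,
    paired_ttest,
    pearson_corr,
    posthoc_ttests,
    rm_anova_mixed,
    rm_anova_prepost,
    top_edges,
)


def gg_epsilon_reference(S):
    """Textbook epsilon via an explicit orthonormal contrast basis."""
    k = S.shape[0]
    # Helmert-style contrasts, orthonormalized
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1)
        C[i] /= np.linalg.norm(C[i])
    M = C @ S @ C.T
    return np.trace(M) ** 2 / ((k - 1) * np.trace(M @ M))


class TestGGEpsilon:
    def test_compound_symmetry_gives_exactly_one(self):
        S = np.full((6, 6), 0.3)
        np.fill_diagonal(S, 1.0)
        assert gg_epsilon(S) == 1.0

    def test_two_levels_always_one(self, rng):
        a = rng.standard_normal((20, 2))
        assert gg_epsilon(np.cov(a, rowvar=False)) == 1.0

    def test_matches_contrast_formula_oracle(self):
        S = np.array([[4.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 0.25]])
        assert gg_epsilon(S) == pytest.approx(gg_epsilon_reference(S), abs=1e-10)

    def test_lower_bound_clip(self):
        S = np.diag([100.0, 0.001, 0.001, 0.001])
        eps = gg_epsilon(S)
        assert 1 / 3 <= eps <= 1

    def test_asymmetric_rejected(self):
        S = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            gg_epsilon(S)


def split_plot_oracle(x, groups):
    """Independent route: pingouin's mixed-design ANOVA on long-format data."""
    import pingouin as pg

    n, k = x.shape
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "node": np.tile(np.arange(k), n),
        "group": np.repeat(list(groups), k),
        "y": x.ravel(),
    })
    aov = pg.mixed_anova(df, dv="y", within="node", subject="subject",
                         between="group")
    return aov


class TestMixedAnova:
    @pytest.mark.parametrize("sizes", [(8, 8), (9, 6)])
    def test_f_matches_independent_oracle(self, rng, sizes):
        n1, n2 = sizes
        x = rng.standard_normal((n1 + n2, 5)) + np.arange(5) * 0.3
        x[:n1] += 0.5
        groups = ["control"] * n1 + ["patient"] * n2
        mine = rm_anova_mixed(x, groups)
        aov = split_plot_oracle(x, groups)
        for res, row in zip(mine, aov.itertuples()):
            assert res.F == pytest.approx(row.F, abs=1e-8)
            assert res.eta_sq == pytest.approx(row.np2, abs=1e-8)
        assert mine[0].df1 == 1 and mine[0].df2 == n1 + n2 - 2
        assert mine[1].df1 == 4

    def test_location_invariance(self, rng):
        x = rng.standard_normal((12, 4))
        groups = ["control"] * 6 + ["patient"] * 6
        a = rm_anova_mixed(x, groups)
        b = rm_anova_mixed(x + 17.3, groups)
        for ra, rb in zip(a, b):
            assert ra.F == pytest.approx(rb.F, rel=1e-9)

    def test_group_relabel_leaves_f_unchanged(self, rng):
        x = rng.standard_normal((10, 4))
        g1 = ["control"] * 5 + ["patient"] * 5
        g2 = ["patient"] * 5 + ["control"] * 5
        for ra, rb in zip(rm_anova_mixed(x, g1), rm_anova_mixed(x, g2)):
            assert ra.F == pytest.approx(rb.F, rel=1e-9)

    def test_missing_cells_rejected(self):
        x = np.zeros((6, 4))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_mixed(x, ["control"] * 3 + ["patient"] * 3)

    def test_single_subject_group_rejected(self, rng):
        x = rng.standard_normal((4, 4))
        with pytest.raises(ValueError):
            rm_anova_mixed(x, ["control"] * 3 + ["patient"])


class TestPrepostAnova:
    def test_identical_sessions_give_zero_treatment_f(self, rng):
        pre = rng.standard_normal((8, 5))
        res = rm_anova_prepost(pre, pre.copy())
        treat = next(r for r in res if r.effect == "treatment")
        assert treat.F == 0.0 and treat.p_gg == 1.0

    def test_f_matches_two_way_rm_oracle(self, rng):
        import pingouin as pg

        n, k = 10, 4
        pre = rng.standard_normal((n, k))
        post = pre + 0.4 + rng.standard_normal((n, k)) * 0.5
        mine = rm_anova_prepost(pre, post)
        rows = []
        for s in range(n):
            for a, tab in [(0, pre), (1, post)]:
                for j in range(k):
                    rows.append({"subject": s, "treat": a, "node": j, "y": tab[s, j]})
        aov = pg.rm_anova(pd.DataFrame(rows), dv="y", within=["treat", "node"],
                          subject="subject", detailed=True)
        for res, row in zip(mine, aov.itertuples()):
            assert res.F == pytest.approx(row.F, abs=1e-8)

    def test_consistent_node_permutation_invariance(self, rng):
        pre = rng.standard_normal((6, 5))
        post = pre + rng.standard_normal((6, 5)) * 0.3
        perm = rng.permutation(5)
        a = rm_anova_prepost(pre, post)
        b = rm_anova_prepost(pre[:, perm], post[:, perm])
        for ra, rb in zip(a, b):
            assert ra.F == pytest.approx(rb.F, rel=1e-9)

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_prepost(np.zeros((5, 4)), np.zeros((6, 4)))


class TestBhFdr:
    def test_step_up_example(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.2]
        q, reject = bh_fdr(p)
        assert list(reject) == [True, True, True, True, False]

    def test_flat_half_rejects_nothing(self):
        q, reject = bh_fdr([0.5] * 8)
        assert not reject.any()

    def test_single_test_is_uncorrected(self):
        q, reject = bh_fdr([0.04])
        assert q[0] == pytest.approx(0.04) and reject[0]

    def test_rejections_monotone_in_threshold(self, rng):
        p = rng.uniform(0, 1, 40)
        r_tight = bh_fdr(p, 0.01)[1]
        r_loose = bh_fdr(p, 0.10)[1]
        assert set(np.flatnonzero(r_tight)) <= set(np.flatnonzero(r_loose))

    def test_q_at_least_p(self, rng):
        p = rng.uniform(0, 1, 30)
        q, _ = bh_fdr(p)
        assert np.all(q >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def gated_anova(band="beta", p=0.001):
    return [AnovaResult(band=band, effect="group x node", F=5.0, df1=15, df2=300,
                        ss_effect=1, ss_error=1, epsilon=0.5, p_unc=p, p_gg=p,
                        eta_sq=0.1)]


class TestPosthoc:
    def test_ungated_band_refused(self, rng):
        x = rng.standard_normal((10, 4))
        anova = gated_anova(p=0.5)
        with pytest.raises(GatingError):
            posthoc_ttests(x, "beta", list("abcd"), anova,
                           groups=["control"] * 5 + ["patient"] * 5)

    def test_group_contrast_direction_and_t(self, rng):
        x = rng.standard_normal((20, 3)) * 0.1
        x[10:, 0] += 2.0  # patients higher at electrode a
        res = posthoc_ttests(x, "beta", list("abc"), gated_anova(),
                             groups=["control"] * 10 + ["patient"] * 10)
        assert res[0].direction == 1 and res[0].significant
        t_ref = sps.ttest_ind(x[10:, 0], x[:10, 0]).statistic
        assert res[0].t == pytest.approx(t_ref)

    def test_constant_equal_groups_give_zero_t(self):
        x = np.ones((8, 2))
        res = posthoc_ttests(x, "beta", list("ab"), gated_anova(),
                             groups=["control"] * 4 + ["patient"] * 4)
        assert all(r.t == 0 and not r.significant for r in res)

    def test_paired_contrast(self, rng):
        pre = rng.standard_normal((12, 3))
        post = pre.copy()
        post[:, 1] += 1.0
        res = posthoc_ttests(pre, "gamma", list("abc"), gated_anova("gamma"),
                             paired_post=post)
        assert res[1].direction == 1 and res[1].significant
        assert res[0].t == pytest.approx(0.0)

    def test_exactly_one_design_required(self, rng):
        x = rng.standard_normal((4, 2))
        with pytest.raises(ValueError):
            posthoc_ttests(x, "beta", list("ab"), gated_anova())


class TestCorrAndTtest:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_corr(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        r_ref = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pearson_corr(x, y).r == pytest.approx(r_ref, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(5), np.arange(5.0))

    def test_paired_identical_gives_t_zero_p_one(self):
        t, df, p = paired_ttest(np.arange(5.0), np.arange(5.0))
        assert t == 0.0 and p == 1.0 and df == 4

    def test_constant_nonzero_difference_degenerates(self):
        t, df, p = paired_ttest(np.zeros(6), np.full(6, 2.0))
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_t_distribution_oracle(self, rng):
        pre = rng.standard_normal(14)
        post = pre + 0.5 + rng.standard_normal(14) * 0.8
        t, df, p = paired_ttest(pre, post)
        d = post - pre
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(14))
        p_ref = 2 * sps.t.sf(abs(t_ref), 13)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestTopEdges:
    def make_pli(self, rng, n=16):
        m = rng.uniform(0, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_fraction_counts(self, rng):
        labels = [f"e{i:02d}" for i in range(16)]
        m = self.make_pli(rng)
        assert len(top_edges(m, labels, 0.2)) == 24
        assert len(top_edges(m, labels, 1.0)) == 120

    def test_selected_edges_are_the_strongest(self, rng):
        labels = [f"e{i:02d}" for i in range(16)]
        m = self.make_pli(rng)
        sel = top_edges(m, labels, 0.2)
        cutoff = min(v for _, _, v in sel)
        others = [m[i, j] for i in range(16) for j in range(i + 1, 16)]
        assert sum(v >= cutoff for v in others) >= len(sel)

    def test_all_equal_ties_resolved_lexicographically(self):
        labels = ["b", "a", "c"]
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 0)
        sel = top_edges(m, labels, 0.4)  # ceil(0.4*3) = 2
        assert sel == [("a", "b", 0.5), ("a", "c", 0.5)]

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            top_edges(np.zeros((3, 3)), list("abc"), 0.0)


def test_interaction_fdr_across_bands_scope():
    anova = []
    for band, p in zip(["delta", "theta", "alpha", "beta", "gamma"],
                       [0.9, 0.8, 0.7, 0.001, 0.04]):
        anova += [AnovaResult(band=band, effect="group", F=1, df1=1, df2=28,
                              ss_effect=1, ss_error=1, epsilon=1.0, p_unc=0.5,
                              p_gg=0.5, eta_sq=0.0),
                  AnovaResult(band=band, effect="group x node", F=1, df1=15,
                              df2=420, ss_effect=1, ss_error=1, epsilon=0.5,
                              p_unc=p, p_gg=p, eta_sq=0.0)]
    fdr_across_bands(anova)
    inter = [a for a in anova if a.effect == "group x node"]
    qs, _ = bh_fdr([a.p_gg for a in inter])
    assert [a.p_fdr_bands for a in inter] == pytest.approx(list(qs))
    assert all(a.p_fdr_bands is None for a in anova if a.effect == "group")
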