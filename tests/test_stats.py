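from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import geomxpurity as gp
from geomxpurity.stats import (
    bh_fdr,
    emmeans_tukey,
    fit_random_intercept,
    median_of_ratios_size_factors,
    nb_wald_de,
    pseudobulk,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank_exact,
)
from geomxpurity.synthetic import simulate_pseudobulk_counts


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

class TestPseudobulk:
    def test_sums_counts_per_tumor(self, small_cohort):
        dataset, *_ = small_cohort
        sox2 = dataset.segment_aois("SOX2")
        pb = pseudobulk(dataset, sox2, "SOX2")
        meta = dataset.aoi_meta.loc[sox2]
        for tumor in pb.index:
            aois = meta.index[meta["tumor_id"] == tumor]
            expected = dataset.counts[list(aois)].sum(axis=1)
            np.testing.assert_array_equal(pb.loc[tumor].to_numpy(), expected.to_numpy())

    def test_single_aoi_tumor_identity(self, small_cohort):
        dataset, *_ = small_cohort
        sox2 = dataset.segment_aois("SOX2")
        one = [sox2[0]]
        pb = pseudobulk(dataset, one, "SOX2")
        tumor = dataset.aoi_meta.loc[sox2[0], "tumor_id"]
        np.testing.assert_array_equal(
            pb.loc[tumor].to_numpy(), dataset.counts[sox2[0]].to_numpy()
        )

    def test_no_surviving_aois_is_an_error(self, small_cohort):
        dataset, *_ = small_cohort
        with pytest.raises(ValueError, match="no surviving"):
            pseudobulk(dataset, [], "SOX2")


# ---------------------------------------------------------------------------
# negative-binomial DE
# ---------------------------------------------------------------------------

class TestNBWaldDE:
    def test_size_factors_are_label_free_and_positive(self):
        counts, cond, _ = simulate_pseudobulk_counts(seed=4, n_genes=400)
        de1 = nb_wald_de(counts, cond)
        permuted = pd.Series(
            np.random.default_rng(0).permutation(cond.to_numpy()), index=cond.index
        )
        de2 = nb_wald_de(counts, permuted)
        pd.testing.assert_series_equal(de1.size_factors, de2.size_factors)
        sf = de1.size_factors.to_numpy()
        assert (sf > 0).all()
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_doubling_counts_is_absorbed_by_size_factors(self):
        counts, cond, _ = simulate_pseudobulk_counts(seed=8, n_genes=300)
        de1 = nb_wald_de(counts, cond)
        de2 = nb_wald_de(counts * 2, cond)
        # ratios to the geometric-mean reference are scale-free, so the
        # size factors are unchanged and the fold-change estimates agree
        # up to the (data-dependent) NB dispersion refit
        np.testing.assert_allclose(de2.size_factors, de1.size_factors)
        np.testing.assert_allclose(de2.table["baseMean"], 2 * de1.table["baseMean"])
        np.testing.assert_allclose(
            de1.table["log2FoldChange"], de2.table["log2FoldChange"], atol=0.05
        )
        assert de1.table["log2FoldChange"].corr(de2.table["log2FoldChange"]) > 0.999

    def test_planted_fold_change_recovered(self):
        counts, cond, lfc = simulate_pseudobulk_counts(
            seed=21, n_genes=500, n_lfc_genes=80, log2fc=1.0
        )
        de = nb_wald_de(counts, cond)
        est = de.table.loc[lfc[lfc != 0].index, "log2FoldChange"]
        assert abs(est.median() - 1.0) < 0.2

    def test_all_zero_genes_excluded_and_reported(self):
        counts, cond, _ = simulate_pseudobulk_counts(seed=3, n_genes=50)
        counts["dead"] = 0
        de = nb_wald_de(counts, cond)
        assert de.excluded_genes == ["dead"]
        assert "dead" not in de.table.index

    def test_qvalues_monotone_in_pvalues(self):
        counts, cond, _ = simulate_pseudobulk_counts(seed=9, n_genes=300)
        tab = nb_wald_de(counts, cond).table.sort_values("pvalue")
        assert tab["qvalue"].is_monotonic_increasing
        assert (tab["qvalue"] >= tab["pvalue"] - 1e-12).all()

    def test_agrees_with_deseq2_reference(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, cond, _ = simulate_pseudobulk_counts(
            seed=5, n_genes=300, n_lfc_genes=60, log2fc=1.0
        )
        meta = pd.DataFrame({"condition": cond})
        dds = DeseqDataSet(
            counts=counts.astype(int), metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "treated", "control"], quiet=True)
        ds.summary()
        mine = nb_wald_de(counts, cond).table
        both = mine.join(ds.results_df[["log2FoldChange"]], rsuffix="_ref").dropna()
        diff = (both["log2FoldChange"] - both["log2FoldChange_ref"]).abs()
        assert diff.median() < 0.01
        assert both["log2FoldChange"].corr(both["log2FoldChange_ref"]) > 0.999

    def test_fallback_size_factors_with_sparse_counts(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(0.15, size=(8, 60)),
            index=[f"T{i}" for i in range(8)],
            columns=[f"g{i}" for i in range(60)],
        )
        with pytest.warns(UserWarning, match="positive"):
            sf = median_of_ratios_size_factors(counts.to_numpy())
        assert np.isfinite(sf).all() and (sf > 0).all()


# ---------------------------------------------------------------------------
# random-intercept LMM + emmeans
# ---------------------------------------------------------------------------

def _paired_data(m=10, effect=0.8, sigma_p=2.0, seed=7):
    rng = np.random.default_rng(seed)
    patient = np.repeat([f"P{i}" for i in range(m)], 2)
    group = np.tile(["primary", "recurrent"], m)
    y = (
        np.repeat(rng.normal(0, sigma_p, m), 2)
        + (group == "recurrent") * effect
        + rng.normal(0, 1, 2 * m)
    )
    return pd.Series(y), pd.Series(group), pd.Series(patient)


class TestRandomIntercept:
    def test_paired_design_reproduces_paired_t(self):
        y, group, patient = _paired_data()
        fit = fit_random_intercept(y, group, patient)
        emm = emmeans_tukey(fit)
        d = y[group == "recurrent"].to_numpy() - y[group == "primary"].to_numpy()
        t_ref = sps.ttest_rel(y[group == "recurrent"], y[group == "primary"])
        row = emm.contrasts.iloc[0]
        assert abs(abs(row["t"]) - abs(t_ref.statistic)) < 1e-8
        assert row["df"] == len(d) - 1
        assert row["p_raw"] == pytest.approx(t_ref.pvalue, abs=1e-8)

    def test_zero_between_patient_variance_reduces_to_ols(self):
        rng = np.random.default_rng(11)
        n = 60
        group = pd.Series(np.repeat(["a", "b"], n // 2))
        patient = pd.Series([f"P{i % 15}" for i in range(n)])
        y = pd.Series((group == "b") * 0.5 + rng.normal(0, 1, n))
        fit = fit_random_intercept(y, group, patient)
        ols_means = y.groupby(group).mean()
        assert fit.sigma2_patient < 0.05
        assert abs(fit.beta["a"] - ols_means["a"]) < 1e-3
        assert abs(fit.beta["b"] - ols_means["b"]) < 1e-3

    def test_constant_response_degenerates_cleanly(self):
        y = pd.Series([3.0] * 8)
        group = pd.Series(["a", "b"] * 4)
        patient = pd.Series([f"P{i // 2}" for i in range(8)])
        fit = fit_random_intercept(y, group, patient)
        assert fit.sigma2_resid == 0.0
        emm = emmeans_tukey(fit)
        assert (emm.contrasts["estimate"] == 0).all()
        assert (emm.contrasts["p_tukey"] == 1.0).all()

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        y, group, patient = _paired_data(m=12, seed=3)
        fit = fit_random_intercept(y, group, patient)
        df = pd.DataFrame({"y": y, "g": group, "p": patient})
        ref = smf.mixedlm("y ~ C(g)", df, groups=df["p"]).fit(reml=True)
        assert fit.sigma2_resid == pytest.approx(ref.scale, rel=1e-4)
        assert fit.sigma2_patient == pytest.approx(ref.cov_re.values[0, 0], rel=1e-3)
        est = fit.beta["recurrent"] - fit.beta["primary"]
        assert est == pytest.approx(ref.params["C(g)[T.recurrent]"], abs=1e-6)

    def test_reml_profile_is_locally_optimal(self):
        from geomxpurity.stats import _blockwise_gls

        y, group, patient = _paired_data(m=8, seed=5)
        fit = fit_random_intercept(y, group, patient)
        lam = fit.variance_ratio
        assert lam > 0

        yv = y.to_numpy()
        levels = sorted(group.unique())
        X = np.column_stack([(group == l).to_numpy(float) for l in levels])
        codes, _ = pd.factorize(patient)
        counts = np.bincount(codes).astype(float)
        n, p = X.shape

        def crit(l):
            A, b, quadform, logdetV = _blockwise_gls(yv, X, codes, counts, l)
            beta = np.linalg.solve(A, b)
            qf = quadform(beta)
            return 0.5 * (logdetV + np.linalg.slogdet(A)[1] + (n - p) * np.log(qf))

        assert crit(lam) <= crit(1e-12) + 1e-10
        assert crit(lam) <= crit(lam * 10) + 1e-10


class TestEmmeansTukey:
    def test_two_groups_tukey_equals_raw(self):
        y, group, patient = _paired_data(m=9, seed=13)
        emm = emmeans_tukey(fit_random_intercept(y, group, patient))
        row = emm.contrasts.iloc[0]
        assert row["p_tukey"] == pytest.approx(row["p_raw"], rel=1e-9)

    def test_four_cell_design_contrasts(self):
        rng = np.random.default_rng(2)
        cells = [f"{a}:{s}" for a, s in product(["treated", "control"],
                                                ["primary", "recurrent"])]
        group = pd.Series(np.repeat(cells, 8))
        patient = pd.Series([f"P{i % 16}" for i in range(32)])
        y = pd.Series(rng.normal(0, 1, 32))
        emm = emmeans_tukey(fit_random_intercept(y, group, patient))
        assert len(emm.contrasts) == 6
        assert (emm.contrasts["p_tukey"] >= emm.contrasts["p_raw"] - 1e-12).all()
        for _, row in emm.contrasts.iterrows():
            a, b = row["contrast"].split(" - ")
            assert row["estimate"] == pytest.approx(
                emm.emmeans.loc[a, "emmean"] - emm.emmeans.loc[b, "emmean"]
            )


# ---------------------------------------------------------------------------
# BH correction
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_at_least_p(self, pvals):
        q = bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1 + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# exact Wilcoxon tests
# ---------------------------------------------------------------------------

def brute_force_signed_rank(d):
    """Enumerate all 2^n sign assignments of the |d| ranks."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def brute_force_rank_sum(x, y):
    """Enumerate all C(m+n, m) assignments of the pooled ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    m = len(x)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:m].sum()
    ws = [sum(ranks[list(idx)]) for idx in combinations(range(len(ranks)), m)]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestSignedRank:
    def test_seven_pairs_all_increasing(self):
        res = wilcoxon_signed_rank_exact([1.2, 0.3, 2.0, 0.7, 1.1, 0.5, 0.9])
        assert res.pvalue == pytest.approx(0.015625)
        assert round(res.pvalue, 4) == 0.0156

    def test_single_pair_p_is_one(self):
        assert wilcoxon_signed_rank_exact([1.5]).pvalue == 1.0

    def test_zero_differences_dropped(self):
        with_zeros = wilcoxon_signed_rank_exact([0.0, 1.0, -2.0, 0.0, 3.0])
        without = wilcoxon_signed_rank_exact([1.0, -2.0, 3.0])
        assert with_zeros.pvalue == without.pvalue
        assert with_zeros.n == 3

    def test_all_zero_differences_warn_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank_exact([0.0, 0.0])
        assert res.pvalue == 1.0

    @pytest.mark.parametrize("n", range(2, 11))
    def test_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        d = np.round(rng.normal(0.2, 1, n), 1)  # rounding creates ties
        d = np.where(d == 0, 0.05, d)
        res = wilcoxon_signed_rank_exact(d)
        assert res.pvalue == pytest.approx(brute_force_signed_rank(d), abs=1e-12)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            d = rng.normal(0.3, 1, 12)
            res = wilcoxon_signed_rank_exact(d)
            ref = sps.wilcoxon(d, alternative="two-sided", mode="exact")
            assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)


class TestRankSum:
    def test_hand_enumerated_example(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.pvalue == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("m,n", [(2, 3), (3, 3), (4, 4), (5, 5), (4, 6), (6, 6)])
    def test_matches_brute_force_enumeration(self, m, n):
        rng = np.random.default_rng(m * 10 + n)
        x = rng.normal(0.5, 1, m)
        y = rng.normal(0, 1, n)
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(brute_force_rank_sum(x, y), abs=1e-12)

    def test_ties_use_corrected_normal_approximation(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 3.0, 4.0, 4.0]
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "normal"
        ref = sps.ranksums(x, y)
        assert res.pvalue == pytest.approx(ref.pvalue, abs=0.05)

    def test_large_samples_match_scipy_asymptotics(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0.4, 1, 30)
        y = rng.normal(0, 1, 25)
        res = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)
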