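import numpy as np
import pandas as pd
import pytest

from hbdot.compare import (AnovaResult, anova_tukey, fisher_z, icc_consistency,
                           reproducibility, similarity, spearman_brown,
                           split_half_analysis, split_timeseries)
from hbdot.rsfc import ConnectivityMatrix


def random_connectivity(rng, R=6):
    A = rng.standard_normal((R, R)) * 0.3
    M = np.tanh((A + A.T) / 2)
    np.fill_diagonal(M, 1.0)
    return M


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_maps_to_atanh(self):
        assert fisher_z(0.5) == pytest.approx(0.54931, abs=1e-5)

    def test_unit_correlation_clipped_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestSimilarity:
    def test_self_similarity_is_unity(self, rng):
        M = random_connectivity(rng)
        res = similarity(M, M)
        assert res.r == pytest.approx(1.0)
        assert res.z == pytest.approx(fisher_z(1.0))

    def test_matches_hand_rolled_pearson(self, rng):
        M1 = random_connectivity(rng)
        M2 = np.tanh(1.3 * np.arctanh(np.clip(M1, -0.999, 0.999)))  # monotone map
        np.fill_diagonal(M2, 1.0)
        res = similarity(M1, M2)
        i, j = np.tril_indices(6, -1)
        z1, z2 = fisher_z(M1[i, j]), fisher_z(M2[i, j])
        ref = (np.mean(z1 * z2) - z1.mean() * z2.mean()) / (z1.std() * z2.std())
        assert res.r == pytest.approx(ref, abs=1e-12)

    def test_invariant_to_consistent_permutation(self, rng):
        M1, M2 = random_connectivity(rng), random_connectivity(rng)
        res = similarity(M1, M2)
        p = rng.permutation(6)
        res_p = similarity(M1[np.ix_(p, p)], M2[np.ix_(p, p)])
        assert res.r == pytest.approx(res_p.r, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        M1, M2 = random_connectivity(rng), random_connectivity(rng)
        assert similarity(M1, M2).r == similarity(M2, M1).r

    def test_mismatched_roi_sets_rejected(self, rng):
        C1 = ConnectivityMatrix(np.eye(3), np.array([1, 2, 3]))
        C2 = ConnectivityMatrix(np.eye(3), np.array([1, 2, 4]))
        with pytest.raises(ValueError, match="ROI sets differ"):
            similarity(C1, C2)


class TestICC:
    def test_identical_raters_give_unity(self):
        x = np.tile(np.arange(8, dtype=float)[:, None], (1, 3))
        assert icc_consistency(x, "single") == pytest.approx(1.0)
        assert icc_consistency(x, "average") == pytest.approx(1.0)

    def test_spearman_brown_identity(self, rng):
        for _ in range(10):
            x = rng.standard_normal((12, 4)) + rng.standard_normal((12, 1)) * 2
            c1 = icc_consistency(x, "single")
            ck = icc_consistency(x, "average")
            assert ck == pytest.approx(spearman_brown(c1, 4), abs=1e-12)

    def test_matches_anova_table_oracle(self):
        # 6 items x 2 raters worked fixture
        x = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 9.0],
                      [2.0, 4.0], [7.0, 6.0], [10.0, 7.0]])
        n, k = x.shape
        grand = x.mean()
        ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
        ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((x - grand) ** 2).sum() - ss_rows - ss_cols
        msr = ss_rows / (n - 1)
        mse = ss_err / ((n - 1) * (k - 1))
        ref1 = (msr - mse) / (msr + (k - 1) * mse)
        refk = (msr - mse) / msr
        assert icc_consistency(x, "single") == pytest.approx(ref1, abs=1e-10)
        assert icc_consistency(x, "average") == pytest.approx(refk, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.standard_normal((10, 3)) + 1.5 * rng.standard_normal((10, 1))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(10), 3),
            "raters": np.tile(np.arange(3), 10),
            "scores": x.ravel(),
        })
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        # rows 2 and 5 are the two-way mixed consistency ICCs
        icc_c1 = float(res["ICC"].iloc[2])
        icc_ck = float(res["ICC"].iloc[5])
        assert icc_consistency(x, "single") == pytest.approx(icc_c1, abs=1e-10)
        assert icc_consistency(x, "average") == pytest.approx(icc_ck, abs=1e-10)

    def test_zero_between_item_variance_undefined(self):
        x = np.tile([[1.0, 2.0]], (5, 1))
        assert np.isnan(icc_consistency(x, "single"))


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        g = [np.array([1.0, 2, 3])] * 3
        res = anova_tukey(g)
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_sums_of_squares_oracle(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]),
                  np.array([10.0, 11, 12])]
        res = anova_tukey(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F_ref = (ssb / 2) / (ssw / 6)
        assert res.F == pytest.approx(F_ref, abs=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        from scipy.stats import f_oneway
        groups = [rng.standard_normal(7) + m for m in (0.0, 0.5, 1.0)]
        res = anova_tukey(groups)
        ref = f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_tukey_matches_statsmodels_unequal_n(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        groups = [rng.standard_normal(n) + m
                  for n, m in ((5, 0.0), (8, 1.0), (6, 0.3))]
        res = anova_tukey(groups, labels=["a", "b", "c"])
        data = np.concatenate(groups)
        labels = np.concatenate([[lab] * len(g) for lab, g in
                                 zip("abc", groups)])
        tk = sm.pairwise_tukeyhsd(data, labels)
        ref_p = {frozenset((g1, g2)): p for g1, g2, p in
                 zip(tk._results_table.data[1:][0] if False else
                     [r[0] for r in tk.summary().data[1:]],
                     [r[1] for r in tk.summary().data[1:]],
                     tk.pvalues)}
        for _, row in res.pairwise.iterrows():
            key = frozenset((row.group1, row.group2))
            assert row.p_adj == pytest.approx(ref_p[key], abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            anova_tukey([np.array([1.0]), np.array([2.0, 3.0])])


class TestSplitHalf:
    def _subjects(self, rng, n=4, T=240, R=5, copy_runs=False):
        subs = {}
        for s in range(n):
            mix = rng.standard_normal((R, R))
            run1 = rng.standard_normal((T, R)) @ mix
            run2 = run1.copy() if copy_runs else rng.standard_normal((T, R)) @ mix
            subs[s] = {"run1": run1, "run2": run2}
        return subs

    def test_midpoint_split_gives_first_half_extra_sample(self):
        fh, sh = split_timeseries(np.zeros((11, 2)))
        assert len(fh) == 6 and len(sh) == 5

    def test_duplicated_runs_make_inter_designs_exact(self, rng):
        """With run2 an exact copy of run1, the half-length inter-run
        designs compare a half with itself (perfect reproducibility) and
        the two intra-run designs coincide."""
        subs = self._subjects(rng, copy_runs=True)
        reports, info = split_half_analysis(subs)
        np.testing.assert_allclose(reports["inter_FH"].r, 1.0, atol=1e-9)
        np.testing.assert_allclose(reports["inter_SH"].r, 1.0, atol=1e-9)
        np.testing.assert_allclose(reports["intra_run1"].r,
                                   reports["intra_run2"].r, atol=1e-12)

    def test_stationary_subjects_show_no_intra_inter_difference(self, rng):
        subs = self._subjects(rng, n=10, T=2000)
        reports, info = split_half_analysis(subs)
        assert abs(info["intra_mean_r"] - info["inter_mean_r"]) < 0.1
        assert info["p"] > 0.05

    def test_short_halves_excluded(self, rng):
        subs = self._subjects(rng, n=3, T=240)
        subs[0]["run1"] = subs[0]["run1"][:20]
        reports, info = split_half_analysis(subs, min_samples=50)
        assert info["excluded_subjects"] == [0]
        assert len(reports["intra_run1"].r) == 2


class TestReproducibility:
    def test_reports_and_summary_shape(self, rng):
        pairs = []
        for _ in range(5):
            M = random_connectivity(rng)
            noisy = np.clip(M + 0.05 * rng.standard_normal(M.shape), -1, 1)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 1.0)
            pairs.append((M, noisy))
        rep = reproducibility(pairs, "inter_run")
        s = rep.summary()
        assert len(rep.r) == 5
        assert rep.icck[0] == pytest.approx(
            spearman_brown(rep.icc1[0], 2), abs=1e-12)
        assert 0 < s["r_mean"] <= 1
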