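"""Transformations, Bray-Curtis, ANOSIM, SIMPER, NMDS, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ferronich import stats
from ferronich.stats import (
    SimilarityMatrix,
    anosim,
    bray_curtis,
    nmds,
    ols_r2,
    pca,
    simper,
    transform_matrix,
)


def _random_counts(rng, n=8, p=12):
    df = pd.DataFrame(
        rng.integers(0, 30, size=(n, p)).astype(float),
        index=[f"s{i}" for i in range(n)],
        columns=[f"g{j}" for j in range(p)],
    )
    labels = {f"s{i}": ("A" if i < n // 2 else "B") for i in range(n)}
    return df, labels


class TestTransforms:
    @pytest.mark.parametrize(
        "t,x,expected",
        [("log", 0.0, 0.0), ("log", 99.0, 2.0), ("sqrt", 4.0, 2.0),
         ("exp", 0.0, 1.0), ("none", 7.0, 7.0)],
    )
    def test_elementwise_values(self, t, x, expected):
        df = pd.DataFrame({"c": [x]})
        assert transform_matrix(df, t).iloc[0, 0] == pytest.approx(expected)

    def test_per_column_spec(self):
        df = pd.DataFrame({"lat": [4.0], "depth": [99.0]})
        out = transform_matrix(df, {"lat": "sqrt", "depth": "log"})
        assert out.iloc[0, 0] == 2.0 and out.iloc[0, 1] == 2.0

    def test_negative_under_log_names_location(self):
        df = pd.DataFrame({"c": [1.0, -2.0]}, index=["r1", "r2"])
        with pytest.raises(ValueError, match="r2.*'c'"):
            transform_matrix(df, "log")


class TestBrayCurtis:
    def test_direct_evaluation(self):
        df = pd.DataFrame([[3, 1, 0], [1, 1, 2]], index=["j", "k"])
        assert bray_curtis(df).S[0, 1] == pytest.approx(50.0)

    def test_identical_rows_full_similarity(self):
        df = pd.DataFrame([[2, 5, 1]] * 2, index=["a", "b"])
        assert bray_curtis(df).S[0, 1] == pytest.approx(100.0)

    def test_disjoint_support_zero(self):
        df = pd.DataFrame([[3, 0], [0, 4]], index=["a", "b"])
        assert bray_curtis(df).S[0, 1] == pytest.approx(0.0)

    def test_matches_scipy_pdist(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            df, _ = _random_counts(rng)
            S = bray_curtis(df).S
            d_scipy = squareform(pdist(df.values, metric="braycurtis"))
            assert np.allclose(100.0 * (1.0 - d_scipy), S, atol=1e-9)

    def test_joint_absences_have_no_effect(self):
        rng = np.random.default_rng(1)
        df, _ = _random_counts(rng)
        S1 = bray_curtis(df).S
        df2 = df.copy()
        df2["absent"] = 0.0
        assert np.allclose(bray_curtis(df2).S, S1)

    def test_all_zero_pair_defined_as_zero_with_warning(self):
        df = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=list("abc"))
        with pytest.warns(UserWarning):
            S = bray_curtis(df).S
        assert S[0, 1] == 0.0


class TestAnosim:
    def _sep(self, n=8):
        ids = [f"s{i}" for i in range(n)]
        labels = {s: ("A" if i < n // 2 else "B") for i, s in enumerate(ids)}
        S = np.full((n, n), 90.0)
        for i in range(n // 2):
            for j in range(n // 2, n):
                S[i, j] = S[j, i] = 10.0
        np.fill_diagonal(S, 100.0)
        return SimilarityMatrix(ids, S), labels

    def test_maximal_separation_gives_R_one(self):
        sim, labels = self._sep()
        r = anosim(sim, labels, n_perm=199, seed=0)
        assert r.R == pytest.approx(1.0)
        assert r.M == 28

    def test_minimum_significance_when_R_beats_all_permutations(self):
        # strict separation over 2 x 8 samples with distinct dissimilarities:
        # no sampled permutation reproduces the partition, so the significance
        # reaches its floor 1/(T+1)
        from ferronich.validation import anosim_construction_checks

        r_max, r_const = anosim_construction_checks(n_perm=199, seed=0)
        assert r_max.R == pytest.approx(1.0)
        assert r_max.n_extreme == 0
        assert r_max.significance == pytest.approx(1 / 200)
        assert r_const.R == pytest.approx(0.0)

    def test_constant_dissimilarities_R_zero(self):
        ids = [f"s{i}" for i in range(8)]
        labels = {s: ("A" if i < 4 else "B") for i, s in enumerate(ids)}
        S = np.full((8, 8), 50.0)
        np.fill_diagonal(S, 100.0)
        assert anosim(SimilarityMatrix(ids, S), labels, 99, 0).R == pytest.approx(0.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        df, labels = _random_counts(rng)
        sim = bray_curtis(df)
        r1 = anosim(sim, labels, n_perm=49, seed=3)
        # strictly increasing transform of the dissimilarities
        D = sim.dissimilarity
        D2 = np.sqrt(D) * 7.0 + np.log1p(D)
        np.fill_diagonal(D2, 0.0)
        sim2 = SimilarityMatrix(sim.ids, 100.0 - D2)
        r2 = anosim(sim2, labels, n_perm=49, seed=3)
        assert r1.R == pytest.approx(r2.R, abs=1e-12)

    def test_matches_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        for _ in range(5):
            df, labels = _random_counts(rng)
            sim = bray_curtis(df)
            mine = anosim(sim, labels, n_perm=9, seed=0)
            dm = skbio_distance.DistanceMatrix(
                sim.dissimilarity / 100.0, ids=sim.ids
            )
            ref = skbio_distance.anosim(
                dm, grouping=[labels[i] for i in sim.ids], permutations=9
            )
            assert mine.R == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_pairwise_mode_restricts_to_pair(self):
        sim, labels = self._sep()
        labels = dict(labels)
        # add a third group by relabeling two samples
        labels["s0"] = labels["s1"] = "C"
        r = anosim(sim, labels, n_perm=99, seed=1, pairwise=True)
        assert {(a, b) for a, b, _, _ in r.pairwise} == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_small_group_rejected(self):
        sim, labels = self._sep()
        labels = dict(labels)
        labels["s0"] = "C"
        with pytest.raises(ValueError):
            anosim(sim, labels, 9, 0)


class TestSimper:
    def test_single_pair_direct_evaluation(self):
        df = pd.DataFrame([[3, 1, 0], [1, 1, 2]], index=["j", "k"],
                          columns=["g1", "g2", "g3"])
        st = simper(df, {"j": "A", "k": "B"}, ("A", "B"))
        got = st.table["mean_contribution"].sort_index()
        assert list(got.round(9)) == [25.0, 0.0, 25.0]
        assert st.overall_dissimilarity == pytest.approx(50.0)

    def test_decomposition_sums_to_bray_curtis_dissimilarity(self):
        rng = np.random.default_rng(5)
        df, labels = _random_counts(rng)
        st = simper(df, labels, ("A", "B"))
        # mean over pairs of (100 - S_jk)
        S = bray_curtis(df).S
        ia = [i for i, s in enumerate(df.index) if labels[s] == "A"]
        ib = [i for i, s in enumerate(df.index) if labels[s] == "B"]
        mean_d = np.mean([100.0 - S[j, k] for j in ia for k in ib])
        assert st.overall_dissimilarity == pytest.approx(mean_d, abs=1e-9)
        assert st.table["mean_contribution"].sum() == pytest.approx(mean_d, abs=1e-9)

    def test_jointly_absent_gene_contributes_zero(self):
        df = pd.DataFrame([[3, 0], [1, 0], [2, 0], [5, 0]],
                          index=list("abcd"), columns=["g1", "g2"])
        labels = {"a": "A", "b": "A", "c": "B", "d": "B"}
        st = simper(df, labels, ("A", "B"))
        assert st.table.loc["g2", "mean_contribution"] == 0.0
        assert st.table.loc["g2", "ratio"] == 0.0

    def test_zero_sd_with_positive_mean_gives_inf_sentinel(self):
        # one cross pair only: SD over pairs is 0 while contribution > 0
        df = pd.DataFrame([[3, 1], [1, 3]], index=["a", "b"], columns=["g1", "g2"])
        st = simper(df, {"a": "A", "b": "B"}, ("A", "B"))
        assert np.isinf(st.table.loc["g1", "ratio"])

    def test_cumulative_percentages_reach_100(self):
        rng = np.random.default_rng(6)
        df, labels = _random_counts(rng)
        st = simper(df, labels, ("A", "B"))
        assert st.table["cumulative_pct"].iloc[-1] == pytest.approx(100.0)
        assert st.table["mean_contribution"].is_monotonic_decreasing

    def test_identical_groups_rejected(self):
        df = pd.DataFrame([[1], [2]], index=["a", "b"])
        with pytest.raises(ValueError):
            simper(df, {"a": "A", "b": "A"}, ("A", "A"))


class TestNmds:
    def test_three_points_embed_exactly(self):
        D = np.array([[0, 30, 40], [30, 0, 50], [40, 50, 0]], float)
        emb = nmds(SimilarityMatrix(list("abc"), 100 - D), n_restarts=10, seed=0)
        assert emb.stress < 1e-6

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 2))
        D = squareform(pdist(X))
        D = 90.0 * D / D.max()
        emb = nmds(SimilarityMatrix([f"p{i}" for i in range(10)], 100 - D),
                   n_restarts=20, seed=1)
        assert emb.stress < 0.01

    def test_equidistant_four_points_cannot_be_planar(self):
        D = np.full((4, 4), 40.0)
        np.fill_diagonal(D, 0.0)
        emb = nmds(SimilarityMatrix(list("abcd"), 100 - D), n_restarts=10, seed=2)
        assert emb.stress > 0.0

    def test_reported_stress_matches_recomputation(self):
        rng = np.random.default_rng(8)
        df, _ = _random_counts(rng)
        sim = bray_curtis(df)
        emb = nmds(sim, n_restarts=5, seed=3)
        re = stats.kruskal_stress(emb.coordinates, sim.condensed_dissimilarity())
        assert emb.stress == pytest.approx(re, abs=1e-9)

    def test_too_few_samples_rejected(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            nmds(SimilarityMatrix(["a", "b"], 100 - D), dims=2)


class TestPca:
    def test_single_direction_of_variation(self):
        t = np.linspace(0, 1, 12)
        df = pd.DataFrame({"x": 2 * t, "y": -3 * t})
        res = pca(df, normalize=False)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_variance_explained_sums_to_one(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("wxyz"))
        res = pca(df, normalize=True)
        assert res.variance_explained.sum() == pytest.approx(1.0)
        # components orthonormal
        L = res.loadings.values
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-9)

    def test_two_variable_closed_form(self):
        # correlation matrix [[1, r], [r, 1]] has eigenvectors (1,1)/sqrt2 and
        # (1,-1)/sqrt2 with eigenvalues 1 +/- r
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        y = 0.8 * x + 0.6 * rng.normal(size=200)
        df = pd.DataFrame({"x": x, "y": y})
        res = pca(df, normalize=True)
        r = np.corrcoef(x, y)[0, 1]
        assert np.allclose(np.abs(res.loadings["PC1"]), 1 / np.sqrt(2), atol=1e-9)
        assert res.variance_explained[0] == pytest.approx((1 + r) / 2, abs=1e-9)

    def test_constant_variable_rejected_under_normalize(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="'c'"):
            pca(df, normalize=True)


def test_ols_r2_perfect_line():
    x = np.arange(10.0)
    assert ols_r2(x, 3.0 * x - 1.0) == pytest.approx(1.0)
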