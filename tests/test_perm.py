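"""Permutation inference: PERMANOVA, PCoA, PERMDISP, pairwise testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

import morphodist as md

POINTS_1D = np.array([0.0, 1.0, 3.0, 5.0])
LABELS_AB = np.array(["A", "A", "B", "B"])


def _euclid(X):
    return squareform(pdist(np.atleast_2d(X.T).T if X.ndim == 1 else X))


class TestPermanova:
    def test_worked_example_exact(self):
        """Two 1-D groups {0,1} vs {3,5}: F and R² from the sum-of-squares
        partition, p from exhaustive enumeration of bipartitions."""
        D = np.abs(POINTS_1D[:, None] - POINTS_1D[None, :])
        res = md.permanova(D, LABELS_AB, exact=True)
        assert res.F == pytest.approx(9.8, abs=1e-10)
        assert res.R2 == pytest.approx(12.25 / 14.75, abs=1e-10)
        assert res.p == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert (res.df_model, res.df_resid) == (1, 2)

    def test_equals_classical_anova_f_on_1d(self, rng):
        x = rng.standard_normal(24)
        labels = np.repeat(["a", "b", "c"], 8)
        D = np.abs(x[:, None] - x[None, :])
        res = md.permanova(D, labels, n_perm=19, seed=0)
        F_classic = f_oneway(*[x[labels == g] for g in "abc"]).statistic
        assert res.F == pytest.approx(F_classic, abs=1e-10)

    def test_matches_skbio(self, rng):
        """Independent cross-check against scikit-bio's implementation."""
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        X = rng.standard_normal((30, 4))
        labels = np.repeat(["g1", "g2", "g3"], 10)
        D = squareform(pdist(X))
        mine = md.permanova(D, labels, n_perm=99, seed=1)
        theirs = sk_permanova(DistanceMatrix(D), labels.tolist(), permutations=99)
        assert mine.F == pytest.approx(theirs["test statistic"], abs=1e-8)

    def test_partition_identity_and_relabel_invariance(self, rng):
        X = rng.standard_normal((20, 3))
        D = squareform(pdist(X))
        labels = np.repeat(["x", "y"], 10)
        r1 = md.permanova(D, labels, n_perm=9, seed=0)
        r2 = md.permanova(D, np.where(labels == "x", "u", "v"), n_perm=9, seed=0)
        assert r1.F == pytest.approx(r2.F)
        assert 0.0 <= r1.R2 <= 1.0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_object_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((16, 2))
        labels = np.repeat(["a", "b"], 8)
        D = squareform(pdist(X))
        perm = rng.permutation(16)
        r1 = md.permanova(D, labels, n_perm=9, seed=0)
        r2 = md.permanova(D[np.ix_(perm, perm)], labels[perm], n_perm=9, seed=0)
        assert r1.F == pytest.approx(r2.F, abs=1e-9)

    def test_separated_clusters_hit_p_floor(self, rng):
        A = rng.standard_normal((10, 2)) * 1e-6
        B = rng.standard_normal((10, 2)) * 1e-6 + 100
        D = squareform(pdist(np.vstack([A, B])))
        labels = np.repeat(["a", "b"], 10)
        res = md.permanova(D, labels, n_perm=199, seed=2)
        assert res.p == pytest.approx(1.0 / 200.0)

    def test_small_groups_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            md.permanova(D, ["a", "a", "b"])


class TestPCoA:
    def test_recovers_euclidean_configuration(self, rng):
        X = rng.standard_normal((25, 2))
        res = md.pcoa(squareform(pdist(X)))
        assert np.all(res.eigenvalues >= -1e-8)
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(X, res.coordinates[:, :2])
        assert disparity < 1e-15

    def test_coordinates_centered(self, rng):
        X = rng.standard_normal((12, 3))
        res = md.pcoa(squareform(pdist(X)))
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-10)

    def test_non_euclidean_flags_imaginary_axis(self):
        # hub-and-spoke distances too short for a Euclidean embedding:
        # three points pairwise 2 apart, a fourth at 1.1 from each
        # (Euclidean requires >= 2/sqrt(3) ≈ 1.155)
        D = np.array(
            [
                [0.0, 2.0, 2.0, 1.1],
                [2.0, 0.0, 2.0, 1.1],
                [2.0, 2.0, 0.0, 1.1],
                [1.1, 1.1, 1.1, 0.0],
            ]
        )
        res = md.pcoa(D)
        assert (res.axis_class == "imaginary").any()
        assert res.neg_eigenvalue_mass > 0


class TestPermdisp:
    def test_worked_example_exact(self):
        x = np.array([-1.0, 1.0, -3.0, 3.0])
        D = np.abs(x[:, None] - x[None, :])
        res, prof = md.permdisp(D, LABELS_AB, exact=True)
        assert np.isinf(res.F)
        assert res.p == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert sorted(prof.distances["distance"]) == pytest.approx([1, 1, 3, 3])

    def test_translated_groups_equal_dispersion(self, rng):
        A = rng.standard_normal((20, 2))
        B = A + np.array([50.0, -30.0])
        D = squareform(pdist(np.vstack([A, B])))
        labels = np.repeat(["a", "b"], 20)
        res, _ = md.permdisp(D, labels, n_perm=99, seed=0)
        assert res.F == pytest.approx(0.0, abs=1e-8)
        assert res.p > 0.9

    def test_distances_match_coordinate_space(self, rng):
        X = rng.standard_normal((30, 3))
        labels = np.repeat(["a", "b", "c"], 10)
        D = squareform(pdist(X))
        _, prof = md.permdisp(D, labels, n_perm=9, seed=0)
        for g in "abc":
            sub = X[labels == g]
            direct = np.linalg.norm(sub - sub.mean(axis=0), axis=1)
            got = prof.distances.loc[prof.distances["group"] == g, "distance"].to_numpy()
            assert np.allclose(np.sort(got), np.sort(direct), atol=1e-8)

    def test_detects_dispersion_difference(self, rng):
        A = rng.standard_normal((40, 3))
        B = rng.standard_normal((40, 3)) * 3.0
        D = squareform(pdist(np.vstack([A, B])))
        labels = np.repeat(["a", "b"], 40)
        res, _ = md.permdisp(D, labels, n_perm=199, seed=1)
        assert res.p <= 0.05

    def test_fast_z_mode_agrees_on_f(self, rng):
        X = rng.standard_normal((24, 2))
        labels = np.repeat(["a", "b"], 12)
        D = squareform(pdist(X))
        r1, _ = md.permdisp(D, labels, n_perm=49, seed=0, permute="assignments")
        r2, _ = md.permdisp(D, labels, n_perm=49, seed=0, permute="z")
        assert r1.F == pytest.approx(r2.F)

    def test_spatial_median_mode_runs(self, rng):
        X = rng.standard_normal((20, 2))
        labels = np.repeat(["a", "b"], 10)
        D = squareform(pdist(X))
        res, _ = md.permdisp(D, labels, n_perm=19, seed=0, center="median")
        assert 0 < res.p <= 1


class TestGowerCentroidDistances:
    def test_1d_identity(self):
        # group {0, 2}: centroid at 1, both members at distance 1
        x = np.array([0.0, 2.0])
        D = np.abs(x[:, None] - x[None, :])
        prof = md.dist_to_group_centroid(D, ["g", "g"])
        assert prof.distances["distance"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_identical_objects_zero(self):
        D = np.zeros((4, 4))
        prof = md.dist_to_group_centroid(D, ["g"] * 4)
        assert np.allclose(prof.distances["distance"], 0.0)

    def test_matches_coordinates_for_euclidean(self, rng):
        X = rng.standard_normal((30, 4))
        labels = np.repeat(["a", "b"], 15)
        D = squareform(pdist(X))
        prof = md.dist_to_group_centroid(D, labels)
        for g in "ab":
            sub = X[labels == g]
            direct = np.linalg.norm(sub - sub.mean(axis=0), axis=1)
            got = prof.distances.loc[prof.distances["group"] == g, "distance"].to_numpy()
            assert np.allclose(got, direct, atol=1e-8)


class TestBalancedDownsample:
    def test_sizes(self, rng):
        labels = np.array(["a"] * 10 + ["b"] * 5)
        idx = md.balanced_downsample(labels, 0)
        sub = labels[idx]
        assert (sub == "a").sum() == (sub == "b").sum() == 5

    def test_deterministic(self):
        labels = np.array(["a"] * 20 + ["b"] * 7)
        assert np.array_equal(md.balanced_downsample(labels, 3), md.balanced_downsample(labels, 3))

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            md.balanced_downsample(["a", "a", "b", "c"], 0)


@pytest.fixture(scope="module")
def four_group_D():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((60, 3)) + np.repeat(np.arange(4), 15)[:, None] * 0.5
    return squareform(pdist(X)), np.repeat(["1", "2", "3", "4"], 15)


class TestPairwiseTests:
    def test_six_pairs_both_tests(self, four_group_D):
        D, labels = four_group_D
        out = md.pairwise_tests(D, labels, n_perm=49, seed=1)
        assert len(out) == 12  # 6 pairs x {permanova, permdisp}
        assert out["bonferroni_alpha"].iloc[0] == pytest.approx(0.05 / 6)
        assert set(out["test"]) == {"permanova", "permdisp"}

    def test_p_floor_convention(self, rng):
        A = rng.standard_normal((12, 2)) * 1e-6
        B = rng.standard_normal((12, 2)) * 1e-6 + 50
        D = squareform(pdist(np.vstack([A, B])))
        labels = np.repeat(["1", "2"], 12)
        out = md.pairwise_tests(D, labels, n_perm=1000, seed=1)
        pa = out[out["test"] == "permanova"]["p"].iloc[0]
        assert pa == pytest.approx(1.0 / 1001.0)

    def test_balanced_n_column(self, rng):
        X = rng.standard_normal((30, 2))
        labels = np.array(["1"] * 10 + ["2"] * 20)
        out = md.pairwise_tests(squareform(pdist(X)), labels, n_perm=19, seed=1)
        assert set(out["n"]) == {20}  # down-sampled to 2 x 10

    def test_deterministic_given_seed(self, four_group_D):
        D, labels = four_group_D
        a = md.pairwise_tests(D, labels, n_perm=29, seed=9)
        b = md.pairwise_tests(D, labels, n_perm=29, seed=9)
        pd.testing.assert_frame_equal(a, b)
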