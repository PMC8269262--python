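"""k-medoids, silhouette k-selection, NMDS, and ANOSIM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from metabmodes.feature_tables import ValidationError
from metabmodes.pattern_analysis import (CLARA, KMedoids, anosim,
                                         cluster_modes, nmds, pam_cluster,
                                         select_k_silhouette)
from metabmodes import synthetic_data as sd
from metabmodes.normalization import standardize_to_total


def blobs(centers, n_per, spread, seed=0, ndim=2):
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(np.asarray(c) + rng.normal(0, spread, (n_per, ndim)))
        labels += [i] * n_per
    return np.vstack(pts), np.array(labels)


class TestPam:
    def test_separated_1d_points(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        est = KMedoids(n_clusters=2).fit(X)
        assert est.labels_[0] == est.labels_[1]
        assert est.labels_[2] == est.labels_[3]
        assert est.labels_[0] != est.labels_[2]

    def test_matches_exhaustive_minimum_on_8_points(self, rng):
        for _ in range(25):
            X = rng.uniform(0, 1, (8, 2))
            D = squareform(pdist(X))
            est = pam_cluster(D, k=2)
            brute = min(D[:, [i, j]].min(axis=1).sum()
                        for i, j in itertools.combinations(range(8), 2))
            assert est.inertia_ == pytest.approx(brute)

    def test_k_n_minus_1_pigeonhole(self, rng):
        X = rng.uniform(0, 1, (6, 2))
        est = KMedoids(n_clusters=5).fit(X)
        sizes = np.bincount(est.labels_)
        assert sorted(sizes) == [1, 1, 1, 1, 2]

    def test_objective_never_increases(self, rng):
        # SWAP only ever applies improving swaps: rerunning from the fitted
        # medoids cannot find a better objective
        X = rng.normal(0, 1, (40, 3))
        est = KMedoids(n_clusters=4).fit(X)
        again = KMedoids(n_clusters=4).fit(X)
        assert again.inertia_ == pytest.approx(est.inertia_)
        assert est.n_iter_ < est.max_iter

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValidationError, match="square"):
            KMedoids(n_clusters=2, metric="precomputed").fit(np.ones((3, 2)))
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            KMedoids(n_clusters=2, metric="precomputed").fit(D)
        with pytest.raises(ValueError, match="n_clusters"):
            KMedoids(n_clusters=1).fit(np.zeros((5, 2)))

    def test_sklearn_get_params_round_trip(self):
        est = KMedoids(n_clusters=3, max_iter=50)
        assert KMedoids(**est.get_params()).get_params() == est.get_params()


class TestClara:
    def test_full_draw_equals_pam(self, rng):
        X = rng.normal(0, 1, (30, 2))
        pam = KMedoids(n_clusters=3).fit(X)
        with pytest.warns(UserWarning, match="clamped"):
            clara = CLARA(n_clusters=3, draw_size=100, random_state=0).fit(X)
        assert np.array_equal(clara.medoid_indices_, pam.medoid_indices_)
        assert clara.inertia_ == pytest.approx(pam.inertia_)

    def test_same_seed_same_partition(self):
        X, _ = blobs([(0, 0), (5, 5), (0, 5), (9, 1)], 30, 0.5, seed=1)
        a = CLARA(n_clusters=4, random_state=7).fit(X)
        b = CLARA(n_clusters=4, random_state=7).fit(X)
        assert np.array_equal(a.labels_, b.labels_)

    def test_recovers_planted_blobs(self):
        X, truth = blobs([(0, 0), (5, 5), (0, 5), (9, 1)], 40, 0.3, seed=2)
        est = CLARA(n_clusters=4, random_state=0).fit(X)
        assert adjusted_rand_score(truth, est.labels_) == 1.0


class TestSelectK:
    def test_two_blobs(self):
        X, _ = blobs([(0, 0), (10, 10)], 20, 0.5, seed=3)
        k, curve = select_k_silhouette(X, k_max=5, seed=0)
        assert k == 2

    def test_three_blobs_matches_direct_silhouette(self):
        X, truth = blobs([(0, 0), (10, 0), (5, 9)], 15, 0.4, seed=4)
        k, curve = select_k_silhouette(X, k_max=6, seed=0)
        assert k == 3
        # direct silhouette formula at the true partition
        D = squareform(pdist(X))
        s = []
        for i in range(len(X)):
            a = D[i, truth == truth[i]].sum() / (np.sum(truth == truth[i]) - 1)
            b = min(D[i, truth == g].mean() for g in set(truth) - {truth[i]})
            s.append((b - a) / max(a, b))
        direct = np.mean(s)
        got = curve.set_index("k").loc[3, "avg_silhouette"]
        assert got == pytest.approx(direct, abs=0.02)

    def test_planted_modes_dataset(self):
        table, truth = sd.mode_recovery_dataset(seed=6, n_features=100,
                                                n_samples=20)
        std = standardize_to_total(table)
        k, _ = select_k_silhouette(std.to_numpy(), k_max=8, seed=6)
        assert k == 5


class TestClusterModes:
    def test_not_observed_pseudo_mode(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(0, 1, (20, 6)),
                              index=[f"f{i}" for i in range(20)])
        values.iloc[3] = np.nan
        values.iloc[11] = np.nan
        part = cluster_modes(values, "toy", k=2, seed=0)
        assert part.labels["f3"] == "not_observed"
        assert part.labels["f11"] == "not_observed"
        assert part.labels.notna().all()
        assert set(part.medoids) == {"a", "b"}

    def test_letters_by_size(self):
        X, truth = blobs([(0, 0), (8, 8)], 10, 0.2, seed=5)
        values = pd.DataFrame(np.vstack([X[truth == 0][:8], X[truth == 1]]),
                              index=[f"f{i}" for i in range(18)])
        part = cluster_modes(values, "toy", k=2, seed=0)
        assert part.mode_sizes()["a"] == 10   # the bigger mode is "a"


class TestNmds:
    def test_recovers_exact_2d_configuration(self, rng):
        X = rng.normal(0, 1, (15, 2))
        D = squareform(pdist(X))
        res = nmds(D, ndim=2, n_starts=4, seed=0)
        assert res.stress < 0.01
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_equilateral_triangle_zero_stress(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = nmds(D, ndim=2, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-3)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(0, 1, (12, 4))
        D = squareform(pdist(X))
        assert nmds(D, seed=3).stress == nmds(D, seed=3).stress

    def test_ndim_bound(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValidationError, match="ndim"):
            nmds(D, ndim=3)


class TestAnosim:
    def _toy(self, sizes=(3, 3), sep=10.0, spread=0.3, seed=0):
        centers = [(0, 0), (sep, sep), (0, sep)][:len(sizes)]
        rng = np.random.default_rng(seed)
        pts, labels = [], []
        for i, (c, n) in enumerate(zip(centers, sizes)):
            pts.append(np.asarray(c) + rng.normal(0, spread, (n, 2)))
            labels += [f"g{i}"] * n
        return squareform(pdist(np.vstack(pts))), np.array(labels)

    def test_perfect_separation_r_is_one(self):
        D, labels = self._toy()
        res = anosim(D, labels, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_null_mean_r_near_zero(self, rng):
        D = squareform(pdist(rng.normal(0, 1, (12, 3))))
        rs = []
        for i in range(100):
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            rs.append(anosim(D, labels, n_perm=9, seed=i).r)
        assert abs(np.mean(rs)) < 0.05

    @pytest.mark.parametrize("sizes", [(2, 2), (3, 3)])
    def test_permutation_p_matches_enumeration(self, sizes):
        D, labels = self._toy(sizes=sizes, sep=4.0, spread=1.5, seed=2)
        exact = anosim(D, labels, method="exact")
        perm = anosim(D, labels, n_perm=20000, seed=0)
        assert perm.r == pytest.approx(exact.r)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
        assert abs(perm.p_value - exact.p_value) <= 3 * se + 1e-4

    def test_exact_enumeration_small_n(self):
        # n = 4 (2+2): only 3 distinct splits; perfect separation has the
        # lowest within-rank sum in 1 of 3 -> p = 1/3
        D, labels = self._toy(sizes=(2, 2))
        res = anosim(D, labels, method="exact")
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 3)

    def test_agrees_with_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        D, labels = self._toy(sizes=(4, 4), sep=2.0, spread=1.0, seed=3)
        res = anosim(D, labels, n_perm=999, seed=0)
        ref = skbio_stats.anosim(skbio_stats.DistanceMatrix(D), labels.tolist(),
                                 permutations=0)
        assert res.r == pytest.approx(ref["test statistic"])

    def test_degenerate_grouping_rejected(self):
        D, labels = self._toy(sizes=(3, 3))
        with pytest.raises(ValidationError):
            anosim(D, np.array(["a"] * 6))
        with pytest.raises(ValidationError):
            anosim(D, np.array(["a", "b", "b", "b", "b", "b"]))
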