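"""Mode discovery and ordination: k-medoids (PAM/CLARA), silhouette-based
k selection, nonmetric MDS, and ANOSIM.

A *mode* is a k-medoids cluster of metabolites sharing an abundance pattern
across samples (environmental tables) or organisms (culture tables).
Clustering is Euclidean on the standardized values produced by
:mod:`metabmodes.normalization`.  The cluster count k is chosen at the
first local maximum of the average silhouette width.

:class:`KMedoids` and :class:`CLARA` follow the scikit-learn estimator
protocol (``fit``, ``labels_``, ``medoid_indices_``, ``get_params``) and
compose with sklearn model selection.  PAM is the exact BUILD + SWAP
algorithm with deterministic lowest-index tie-breaking; CLARA repeats PAM
on random subsamples (each augmented with the incumbent medoids) and keeps
the draw with the lowest total dissimilarity over all points.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_samples

from .feature_tables import ValidationError

__all__ = ["KMedoids", "CLARA", "ModePartition", "OrdinationResult",
           "AnosimResult", "pam_cluster", "clara_cluster",
           "select_k_silhouette", "cluster_modes", "nmds", "anosim"]

NOT_OBSERVED = "not_observed"


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {D.shape}")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    return D


class KMedoids(ClusterMixin, BaseEstimator):
    """PAM k-medoids (BUILD + SWAP) with deterministic multi-start.

    The SWAP phase is steepest descent: each pass applies the single best
    improving swap, so the objective never increases.  Steepest descent can
    stop in a swap-local optimum even on small instances (R's reference
    ``cluster::pam`` shows the same behavior), so by default the solver
    also runs SWAP from ``n_init - 1`` seeded random medoid sets and keeps
    the best solution; ``n_init=1`` gives the classical single BUILD start.

    Parameters
    ----------
    n_clusters : int
        Number of medoids k (2 <= k < n).
    metric : {"euclidean", "precomputed"}
        With "precomputed", ``fit`` expects a square dissimilarity matrix.
    max_iter : int
        Cap on SWAP passes per start.
    n_init : int
        Number of starts: the deterministic BUILD start plus ``n_init - 1``
        random ones.
    random_state : int
        Seeds the random starts; the default makes ``fit`` reproducible.

    Attributes
    ----------
    medoid_indices_ : ndarray of shape (k,)
    labels_ : ndarray of shape (n,)
    inertia_ : float
        Total dissimilarity of every point to its nearest medoid.
    n_iter_ : int
        SWAP passes used by the winning start.
    """

    def __init__(self, n_clusters: int = 2, metric: str = "euclidean",
                 max_iter: int = 300, n_init: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.metric = metric
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.metric == "precomputed":
            D = _check_distance_matrix(X)
        elif self.metric == "euclidean":
            D = squareform(pdist(np.asarray(X, dtype=float)))
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        n = D.shape[0]
        k = self.n_clusters
        if not 2 <= k < n:
            raise ValueError(f"need 2 <= n_clusters < n_points, got k={k}, n={n}")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")

        rng = np.random.default_rng(self.random_state)
        starts = [self._build(D, k)]
        for _ in range(self.n_init - 1):
            starts.append(sorted(rng.choice(n, size=k, replace=False).tolist()))

        best = None
        for start in starts:
            medoids, n_iter = self._swap(D, start)
            cost = float(D[:, medoids].min(axis=1).sum())
            key = (cost, sorted(medoids))
            if best is None or key < best[0]:
                best = (key, medoids, n_iter)
        self.medoid_indices_ = np.array(sorted(best[1]))
        d_to_med = D[:, self.medoid_indices_]
        self.labels_ = np.argmin(d_to_med, axis=1)
        self.inertia_ = float(d_to_med.min(axis=1).sum())
        self.n_iter_ = best[2]
        return self

    @staticmethod
    def _build(D: np.ndarray, k: int) -> list[int]:
        n = D.shape[0]
        medoids = [int(np.argmin(D.sum(axis=0)))]     # ties -> lowest index
        d1 = D[:, medoids[0]].copy()
        while len(medoids) < k:
            gains = np.maximum(d1[:, None] - D, 0.0).sum(axis=0)
            gains[medoids] = -np.inf
            h = int(np.argmax(gains))                 # ties -> lowest index
            medoids.append(h)
            d1 = np.minimum(d1, D[:, h])
        return medoids

    def _swap(self, D: np.ndarray, medoids: list[int]) -> tuple[list[int], int]:
        n = D.shape[0]
        medoids = list(medoids)
        for it in range(self.max_iter):
            med = np.array(medoids)
            dm = D[:, med]
            order = np.argsort(dm, axis=1, kind="stable")
            d1 = dm[np.arange(n), order[:, 0]]
            d2 = dm[np.arange(n), order[:, 1]]
            nearest = order[:, 0]

            best_delta = -1e-12
            best_swap = None
            for mi in range(len(med)):
                mask = nearest == mi
                other = ~mask
                # cost change for swapping medoid mi with every candidate h
                gain_other = np.minimum(D[other] - d1[other, None], 0.0).sum(axis=0)
                reassign = (np.minimum(D[mask], d2[mask, None])
                            - d1[mask, None]).sum(axis=0)
                delta = gain_other + reassign
                delta[med] = np.inf
                h = int(np.argmin(delta))       # ties -> lowest index
                if delta[h] < best_delta:
                    best_delta = float(delta[h])
                    best_swap = (mi, h)
            if best_swap is None:
                return medoids, it
            medoids[best_swap[0]] = best_swap[1]
        return medoids, self.max_iter

    def predict(self, X):
        if self.metric == "precomputed":
            raise ValueError("predict is not defined for precomputed distances")
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self._medoid_points_[None], axis=2)
        return np.argmin(d, axis=1)

    def fit_predict(self, X, y=None):
        self.fit(X)
        if self.metric == "euclidean":
            self._medoid_points_ = np.asarray(X, dtype=float)[self.medoid_indices_]
        return self.labels_


class CLARA(ClusterMixin, BaseEstimator):
    """CLARA: PAM on random subsamples, scored on the full dataset.

    Each of ``n_draws`` subsamples (size ``draw_size``, default 40 + 2k)
    is augmented with the incumbent best medoids before PAM; all points
    are then assigned to the nearest resulting medoid and the draw with
    the lowest total dissimilarity wins.  Euclidean distance on rows.
    """

    def __init__(self, n_clusters: int = 2, n_draws: int = 5,
                 draw_size: int | None = None, max_iter: int = 300,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_draws = n_draws
        self.draw_size = draw_size
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        draw_size = self.draw_size if self.draw_size is not None else 40 + 2 * k
        if draw_size < k:
            raise ValueError("draw_size must be >= n_clusters")
        if draw_size > n:
            warnings.warn(f"draw_size {draw_size} > n {n}; clamped to n")
            draw_size = n
        rng = np.random.default_rng(self.random_state)

        best_cost = np.inf
        best_medoids: np.ndarray | None = None
        for _ in range(self.n_draws):
            idx = rng.choice(n, size=draw_size, replace=False)
            if best_medoids is not None:
                idx = np.union1d(idx, best_medoids)
            idx = np.sort(idx)
            pam = KMedoids(n_clusters=k, metric="euclidean",
                           max_iter=self.max_iter).fit(X[idx])
            medoids = idx[pam.medoid_indices_]
            d = np.linalg.norm(X[:, None, :] - X[medoids][None], axis=2)
            cost = float(d.min(axis=1).sum())
            if cost < best_cost:
                best_cost = cost
                best_medoids = medoids
            if draw_size == n:      # degenerate: full PAM, further draws identical
                break
        self.medoid_indices_ = np.sort(best_medoids)
        d = np.linalg.norm(X[:, None, :] - X[self.medoid_indices_][None], axis=2)
        self.labels_ = np.argmin(d, axis=1)
        self.inertia_ = float(d.min(axis=1).sum())
        return self


def pam_cluster(dist: np.ndarray, k: int, max_iter: int = 300) -> KMedoids:
    """Functional wrapper: PAM on a precomputed dissimilarity matrix."""
    return KMedoids(n_clusters=k, metric="precomputed", max_iter=max_iter).fit(dist)


def clara_cluster(data: np.ndarray, k: int, n_draws: int = 5,
                  draw_size: int | None = None, seed: int | None = None) -> CLARA:
    """Functional wrapper: CLARA on a data matrix (rows are observations)."""
    return CLARA(n_clusters=k, n_draws=n_draws, draw_size=draw_size,
                 random_state=seed).fit(data)


def _avg_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from a precomputed distance matrix.

    Singleton clusters get silhouette 0 (scikit-learn's convention, kept
    here as the documented choice).
    """
    return float(silhouette_samples(D, labels, metric="precomputed").mean())


def select_k_silhouette(data: np.ndarray, k_min: int = 2, k_max: int = 8,
                        seed: int | None = None, method: str = "clara",
                        n_draws: int = 5, draw_size: int | None = None,
                        ) -> tuple[int, pd.DataFrame]:
    """Pick k at the first local maximum of average silhouette width.

    Computes the silhouette curve for k in [k_min, k_max] and returns the
    smallest k with s̄(k) > s̄(k-1) and s̄(k) > s̄(k+1) (endpoints compared
    one-sided).  If the curve has no local maximum, the argmax is returned
    with a warning.  The full curve comes back as diagnostics.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if not 2 <= k_min <= k_max < n:
        raise ValueError(f"need 2 <= k_min <= k_max < n, got [{k_min}, {k_max}], n={n}")
    D = squareform(pdist(data))
    ks = list(range(k_min, k_max + 1))
    sils = []
    for k in ks:
        if method == "clara":
            est = CLARA(n_clusters=k, n_draws=n_draws, draw_size=draw_size,
                        random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # draw_size clamping on tiny n
                est.fit(data)
            labels = est.labels_
        elif method == "pam":
            labels = KMedoids(n_clusters=k, metric="precomputed").fit(D).labels_
        else:
            raise ValueError(f"unknown method {method!r}")
        sils.append(_avg_silhouette(D, labels))
    curve = pd.DataFrame({"k": ks, "avg_silhouette": sils})
    s = np.asarray(sils)
    for i, k in enumerate(ks):
        left_ok = (i == 0) or (s[i] > s[i - 1])
        right_ok = (i == len(ks) - 1) or (s[i] > s[i + 1])
        if left_ok and right_ok:
            return k, curve
    warnings.warn("silhouette curve has no local maximum; returning argmax")
    return int(ks[int(np.argmax(s))]), curve


@dataclass
class ModePartition:
    """Assignment of every feature in a dataset to exactly one mode.

    Modes are labeled a, b, c, ... by decreasing size; features absent
    from the dataset occupy the explicit ``not_observed`` pseudo-mode
    rather than being dropped.
    """

    dataset_id: str
    labels: pd.Series                 # feature_id -> mode label
    medoids: dict[str, str]           # mode label -> medoid feature_id
    k: int
    avg_silhouette: float | None = None
    silhouette_curve: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValidationError("partition has duplicate feature ids")
        for mode, medoid in self.medoids.items():
            if self.labels.get(medoid) != mode:
                raise ValidationError(f"medoid {medoid} is not a member of mode {mode}")

    def mode_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, mode: str) -> pd.Index:
        return self.labels.index[self.labels == mode]


def cluster_modes(values: pd.DataFrame, dataset_id: str,
                  k: int | None = None, k_min: int = 2, k_max: int = 8,
                  seed: int | None = None, method: str = "clara",
                  n_draws: int = 5, draw_size: int | None = None,
                  ) -> ModePartition:
    """Cluster standardized feature patterns into modes.

    ``values`` is features × samples (rows are the patterns clustered,
    Euclidean metric).  Features with no observation in this dataset
    (all-missing rows) go to the ``not_observed`` pseudo-mode; remaining
    missing entries are rendered 0.  With ``k=None`` the silhouette rule
    picks k.
    """
    observed_mask = values.notna().any(axis=1)
    observed = values.loc[observed_mask].fillna(0.0)
    X = observed.to_numpy(dtype=float)
    curve = None
    if k is None:
        k, curve = select_k_silhouette(X, k_min=k_min, k_max=k_max, seed=seed,
                                       method=method, n_draws=n_draws,
                                       draw_size=draw_size)
    if method == "clara":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = CLARA(n_clusters=k, n_draws=n_draws, draw_size=draw_size,
                        random_state=seed).fit(X)
    else:
        est = KMedoids(n_clusters=k, metric="euclidean").fit(X)
    D = squareform(pdist(X))
    avg_sil = _avg_silhouette(D, est.labels_)

    # letter labels by decreasing mode size; ties by medoid index
    sizes = pd.Series(est.labels_).value_counts()
    order = sorted(range(k), key=lambda c: (-sizes.get(c, 0), c))
    letters = _mode_letters(k)
    relabel = {c: letters[i] for i, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in est.labels_], index=observed.index)
    medoids = {relabel[c]: observed.index[m]
               for c, m in enumerate(est.medoid_indices_)}
    if (~observed_mask).any():
        labels = pd.concat([labels, pd.Series(
            NOT_OBSERVED, index=values.index[~observed_mask])])
        labels = labels.reindex(values.index)
    return ModePartition(dataset_id=dataset_id, labels=labels, medoids=medoids,
                         k=k, avg_silhouette=avg_sil, silhouette_curve=curve)


def _mode_letters(k: int) -> list[str]:
    letters = list(string.ascii_lowercase)
    out = []
    i = 0
    while len(out) < k:
        out.append(letters[i % 26] * (i // 26 + 1))
        i += 1
    return out


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float                    # Kruskal stress-1
    converged: bool
    seed: int | None


def nmds(dist: np.ndarray, ndim: int = 2, n_starts: int = 4,
         seed: int | None = 0, max_iter: int = 300) -> OrdinationResult:
    """Kruskal nonmetric MDS on a dissimilarity matrix (best of n starts)."""
    D = _check_distance_matrix(dist)
    n = D.shape[0]
    if ndim >= n:
        raise ValidationError(f"ndim ({ndim}) must be < number of points ({n})")
    import inspect
    if "metric_mds" in inspect.signature(MDS.__init__).parameters:
        mds = MDS(n_components=ndim, metric="precomputed", metric_mds=False,
                  n_init=n_starts, init="random", max_iter=max_iter,
                  random_state=seed, normalized_stress=True)
    else:   # scikit-learn < 1.9 spelling
        mds = MDS(n_components=ndim, metric=False, n_init=n_starts,
                  max_iter=max_iter, random_state=seed,
                  dissimilarity="precomputed", normalized_stress=True)
    coords = mds.fit_transform(D)
    coords = coords - coords.mean(axis=0)
    stress = float(mds.stress_)
    converged = bool(getattr(mds, "n_iter_", max_iter) < max_iter)
    return OrdinationResult(coordinates=coords, stress=stress,
                            converged=converged, seed=seed)


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_perm: int
    seed: int | None
    method: str = "permutation"


def _anosim_r(rank_pairs: np.ndarray, within: np.ndarray) -> float:
    M = rank_pairs.size
    return float((rank_pairs[~within].mean() - rank_pairs[within].mean())
                 / (M / 2.0))


def anosim(dist: np.ndarray, groups, n_perm: int = 999,
           seed: int | None = 0, method: str = "permutation") -> AnosimResult:
    """Analysis of similarities on rank dissimilarities.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 pairs; R = 1 means complete separation.  The p-value is
    estimated by permuting group labels, p = (1 + #{R_perm >= R_obs}) /
    (1 + n_perm), or computed exactly by enumerating all distinct label
    arrangements (``method="exact"``, small n only).
    """
    D = _check_distance_matrix(dist)
    labels = np.asarray(groups)
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValidationError("groups length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValidationError("ANOSIM needs >= 2 groups with >= 2 members each")
    iu = np.triu_indices(n, 1)
    ranks = rankdata(D[iu])
    obs = _anosim_r(ranks, labels[iu[0]] == labels[iu[1]])

    if method == "exact":
        if n > 10:
            raise ValidationError("exact enumeration is limited to n <= 10")
        seen = set(itertools.permutations(labels.tolist()))
        hits = sum(_anosim_r(ranks, (p := np.asarray(perm))[iu[0]] == p[iu[1]])
                   >= obs - 1e-12 for perm in seen)
        return AnosimResult(r=obs, p_value=hits / len(seen), n_perm=len(seen),
                            seed=None, method="exact")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm[iu[0]] == perm[iu[1]]) >= obs - 1e-12:
            hits += 1
    return AnosimResult(r=obs, p_value=(1 + hits) / (1 + n_perm),
                        n_perm=n_perm, seed=seed, method="permutation")
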