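"""Base clusterers generating the hard partitions that feed the consensus.

Three methods, mirroring the usual heterogeneous ensemble for expression
time-series: k-means with deterministic Kaufman initialisation, an online
self-organising map with bubble (hard-radius) neighbourhood, and Ward-linkage
hierarchical clustering.  Each is exposed as a scikit-learn style estimator
(``fit`` / ``fit_predict`` / ``labels_``) plus a thin function returning a
:class:`Partition` — a complete hard K x G membership matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "KaufmanKMeans",
    "BubbleSOM",
    "WardClustering",
    "kmeans_ka",
    "som_cluster",
    "hc_ward",
]

try:  # the SOM inner loop is sequential; numba makes the full grid affordable
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is pre-installed in practice
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@dataclass
class Partition:
    """A complete hard partition of ``G`` genes into ``K`` clusters.

    ``membership`` is a K x G binary matrix whose columns each sum to exactly
    one.  ``source`` records (method, dataset_id, K); ``relabelled_to`` is set
    by min-min relabelling and required before consensus averaging.
    """

    K: int
    gene_ids: list[str]
    membership: np.ndarray
    source: tuple = ("", "", 0)
    relabelled_to: str | None = None
    _row_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.uint8)
        if self.K < 2:
            raise InputError("a partition needs K >= 2 clusters")
        if self.membership.shape != (self.K, len(self.gene_ids)):
            raise InputError("membership shape must be (K, G)")
        if not np.all(self.membership.sum(axis=0) == 1):
            raise InputError("every gene must belong to exactly one cluster")
        self._row_index = {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_labels(cls, labels, gene_ids, K: int, source=("", "", 0)) -> "Partition":
        labels = np.asarray(labels, dtype=int)
        M = np.zeros((K, labels.size), dtype=np.uint8)
        M[labels, np.arange(labels.size)] = 1
        return cls(K=K, gene_ids=list(gene_ids), membership=M, source=source)

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.membership, axis=0)

    def cluster_sets(self) -> list[set[str]]:
        lab = self.labels
        return [{g for g, l in zip(self.gene_ids, lab) if l == k} for k in range(self.K)]


def _validate_X(X, K: int) -> np.ndarray:
    X = check_array(X, dtype=float)
    if K < 2:
        raise InputError("K must be >= 2")
    if K > X.shape[0]:
        raise InputError(f"K={K} exceeds the number of points {X.shape[0]}")
    return X


class KaufmanKMeans(BaseEstimator, ClusterMixin):
    """k-means with deterministic Kaufman (KA) seeding and Lloyd iterations.

    The first centre is the point minimising the total Euclidean distance to
    all points; each subsequent centre is the point maximising the summed
    positive reduction of the other points' nearest-centre distances.  Lloyd
    updates (squared-Euclidean assignment, mean centroids) run until the
    assignment stops changing or ``max_iter`` is reached.  An emptied cluster
    is re-seeded with the point farthest from its nearest centre.  There is no
    randomness: the same input always yields the same partition.
    """

    def __init__(self, n_clusters: int = 8, max_iter: int = 300,
                 pairwise_distances: np.ndarray | None = None):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.pairwise_distances = pairwise_distances  # optional precomputed cache

    def fit(self, X, y=None):
        X = _validate_X(X, self.n_clusters)
        G = X.shape[0]
        D = self.pairwise_distances
        if D is None:
            D = cdist(X, X)
        elif D.shape != (G, G):
            raise InputError("precomputed distance matrix has wrong shape")
        centres = [int(np.argmin(D.sum(axis=1)))]
        nearest = D[:, centres[0]].copy()
        for _ in range(1, self.n_clusters):
            gains = np.maximum(0.0, nearest[None, :] - D).sum(axis=1)
            gains[centres] = -np.inf
            c = int(np.argmax(gains))
            centres.append(c)
            np.minimum(nearest, D[:, c], out=nearest)
        C = X[centres].copy()

        labels = np.full(G, -1, dtype=int)
        for it in range(self.max_iter):
            d2 = cdist(X, C, metric="sqeuclidean")
            new_labels = np.argmin(d2, axis=1)
            for k in range(self.n_clusters):  # re-seed emptied clusters
                if not np.any(new_labels == k):
                    far = int(np.argmax(d2[np.arange(G), new_labels]))
                    logger.debug("re-seeding empty cluster %d with point %d", k, far)
                    new_labels[far] = k
                    C[k] = X[far]
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for k in range(self.n_clusters):
                C[k] = X[labels == k].mean(axis=0)
        self.cluster_centers_ = C
        self.labels_ = labels
        self.n_iter_ = it + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _som_grid(K: int) -> tuple[int, int]:
    """Factor pair (r, c), r * c = K, with |r - c| minimal and r <= c."""
    r = int(np.sqrt(K))
    while K % r:
        r -= 1
    return r, K // r


@_njit(cache=False)
def _som_train_loop(W, X, unit_dist, order, radii, lrs):  # pragma: no cover - jitted
    n_updates = order.shape[0]
    K, D = W.shape
    for t in range(n_updates):
        x = X[order[t]]
        best, best_d = 0, 1e300
        for k in range(K):
            d = 0.0
            for j in range(D):
                diff = W[k, j] - x[j]
                d += diff * diff
            if d < best_d:
                best_d, best = d, k
        r, lr = radii[t], lrs[t]
        for k in range(K):
            if unit_dist[best, k] < r:  # strict: the final radius-1 bubble is the BMU alone
                for j in range(D):
                    W[k, j] += lr * (x[j] - W[k, j])
    return W


def _som_train_python(W, X, unit_dist, order, radii, lrs):
    for t in range(order.shape[0]):
        x = X[order[t]]
        best = int(np.argmin(((W - x) ** 2).sum(axis=1)))
        mask = unit_dist[best] < radii[t]
        W[mask] += lrs[t] * (x - W[mask])
    return W


class BubbleSOM(BaseEstimator, ClusterMixin):
    """Online rectangular SOM with bubble neighbourhood, units = clusters.

    The grid is the most-square factorisation of ``n_clusters`` (4x4 for
    K=16).  The bubble neighbourhood updates every unit within the current
    radius at the full learning rate; the radius decays linearly from
    ``max(grid dims)/2`` to 1 and the learning rate from 0.5 to 0.01 over
    ``100 * G`` updates.  Training order is derived from a canonical
    (lexicographic) ordering of the rows so the result is invariant to
    permutations of the input; ``random_state`` seeds the epoch shuffles.
    Units that end empty are retained as empty clusters so K is preserved for
    relabelling.
    """

    def __init__(self, n_clusters: int = 16, updates_per_gene: int = 100,
                 lr_start: float = 0.5, lr_end: float = 0.01, random_state: int = 0):
        self.n_clusters = n_clusters
        self.updates_per_gene = updates_per_gene
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.n_clusters < 2:
            raise InputError("K must be >= 2")
        G, D = X.shape
        K = self.n_clusters
        rows, cols = _som_grid(K)
        gi, gj = np.divmod(np.arange(K), cols)
        pos = np.column_stack([gi, gj]).astype(float)
        unit_dist = cdist(pos, pos)

        canon = np.lexsort(X.T[::-1])  # canonical order: sort rows lexicographically
        rng = np.random.default_rng(self.random_state)
        n_epochs = self.updates_per_gene
        order = np.concatenate([canon[rng.permutation(G)] for _ in range(n_epochs)])
        n_updates = order.size
        frac = np.arange(n_updates) / max(n_updates - 1, 1)
        radii = max(rows, cols) / 2.0 + (1.0 - max(rows, cols) / 2.0) * frac
        lrs = self.lr_start + (self.lr_end - self.lr_start) * frac

        init_idx = canon[np.linspace(0, G - 1, K).round().astype(int)]
        W = X[init_idx].astype(float).copy()
        train = _som_train_loop if _HAVE_NUMBA else _som_train_python
        W = train(W, X, unit_dist, order, radii, lrs)

        self.weights_ = W
        self.grid_shape_ = (rows, cols)
        self.labels_ = np.argmin(cdist(X, W, metric="sqeuclidean"), axis=1)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class WardClustering(BaseEstimator, ClusterMixin):
    """Agglomerative clustering, Euclidean distance, Ward criterion, cut at K.

    A precomputed linkage matrix may be supplied so a single tree can be cut
    at several K values without re-clustering.
    """

    def __init__(self, n_clusters: int = 8, linkage_matrix: np.ndarray | None = None):
        self.n_clusters = n_clusters
        self.linkage_matrix = linkage_matrix

    def fit(self, X, y=None):
        X = _validate_X(X, self.n_clusters)
        Z = self.linkage_matrix if self.linkage_matrix is not None else linkage(X, method="ward")
        self.linkage_matrix_ = Z
        self.labels_ = fcluster(Z, t=self.n_clusters, criterion="maxclust") - 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# Partition-returning wrappers


def _as_partition(labels, K, gene_ids, method, dataset_id) -> Partition:
    if gene_ids is None:
        gene_ids = [str(i) for i in range(len(labels))]
    return Partition.from_labels(labels, gene_ids, K, source=(method, dataset_id, K))


def kmeans_ka(data, K: int, gene_ids=None, dataset_id: str = "") -> Partition:
    """Deterministic Kaufman-initialised k-means partition of the rows of ``data``."""
    labels = KaufmanKMeans(n_clusters=K).fit_predict(data)
    return _as_partition(labels, K, gene_ids, "kmeans_ka", dataset_id)


def som_cluster(data, K: int, gene_ids=None, dataset_id: str = "", seed: int = 0) -> Partition:
    """Bubble-neighbourhood SOM partition; the seed is recorded in the source."""
    labels = BubbleSOM(n_clusters=K, random_state=seed).fit_predict(data)
    p = _as_partition(labels, K, gene_ids, f"som[seed={seed}]", dataset_id)
    return p


def hc_ward(data, K: int, gene_ids=None, dataset_id: str = "") -> Partition:
    """Ward-linkage hierarchical clustering cut into exactly K groups."""
    labels = WardClustering(n_clusters=K).fit_predict(data)
    return _as_partition(labels, K, gene_ids, "hc_ward", dataset_id)
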