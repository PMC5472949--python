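"""Consensus of partitions: min-min relabelling, weighted CoPaM averaging with
missing-gene support, and difference-threshold binarisation (DTB).

The pipeline is the classic four-step consensus: (1) generate ``R = C x L``
hard partitions by applying ``C`` clustering methods to ``L`` datasets;
(2) permute (relabel) every partition's clusters to align with a reference,
matching the best-fitting cluster pairs first (min-min); (3) average the
relabelled membership matrices element-by-element into a fuzzy consensus
partition matrix (CoPaM), averaging each gene only over the partitions whose
dataset actually measures it; (4) binarise with DTB: a gene joins its
max-membership cluster only when that membership exceeds every other cluster's
by at least the tuning parameter ``delta`` (0 = loosest, 1 = most stringent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator

from .cluster import BubbleSOM, KaufmanKMeans, Partition, WardClustering
from .datasets import DatasetCollection
from .errors import InputError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "CoPaM",
    "DTBParams",
    "relabel_min_min",
    "build_copam",
    "dtb_binarise",
    "uncles_type_a",
    "UnclesTypeA",
    "DEFAULT_K_VALUES",
    "DEFAULT_DELTAS",
    "DEFAULT_METHODS",
]

DEFAULT_K_VALUES = (8, 9, 10, 16, 18, 24, 30, 40)
DEFAULT_DELTAS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
DEFAULT_METHODS = ("kmeans_ka", "som", "hc_ward")


@dataclass
class CoPaM:
    """Fuzzy consensus partition matrix over the collection's gene universe.

    ``fuzzy[k, g]`` in [0, 1] is the mean membership of gene ``g`` in cluster
    ``k`` over the partitions whose dataset includes ``g``; ``support[g]``
    counts those partitions.  Columns with positive support sum to one.
    """

    K: int
    gene_ids: list[str]
    fuzzy: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.fuzzy = np.asarray(self.fuzzy, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if self.fuzzy.shape != (self.K, len(self.gene_ids)):
            raise InputError("fuzzy matrix shape must be (K, G)")
        sums = self.fuzzy.sum(axis=0)
        ok = self.support == 0
        if not np.allclose(sums[~ok], 1.0, atol=1e-9):
            raise InputError("supported CoPaM columns must sum to 1")


@dataclass
class DTBParams:
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise InputError("delta must lie in [0, 1]")


def _minmin_matching(cost: np.ndarray) -> np.ndarray:
    """Greedy min-first matching of a K x K cost matrix.

    Repeatedly matches the globally minimal unmatched (i, j) pair; ties break
    to the lowest (i, j) in row-major order.  Returns ``perm`` with
    ``perm[i] = j``: reference cluster i is matched to target cluster j.
    """
    K = cost.shape[0]
    work = cost.astype(float).copy()
    perm = np.full(K, -1, dtype=int)
    for _ in range(K):
        flat = int(np.argmin(work))  # row-major argmin = lowest (i, j) on ties
        i, j = divmod(flat, K)
        perm[i] = j
        work[i, :] = np.inf
        work[:, j] = np.inf
    return perm


def relabel_min_min(reference: Partition, target: Partition) -> Partition:
    """Permute ``target``'s clusters to align with ``reference`` (min-min).

    The matching cost of reference cluster i and target cluster j is the size
    of the symmetric difference of their gene sets restricted to the genes
    shared by both partitions; the fittest (lowest-cost) pairs are matched
    first so the best clusters align even if poor clusters are matched badly.
    An empty cluster's cost against a non-empty one is simply the latter's
    size, so empty clusters participate naturally.
    """
    if reference.K != target.K:
        raise InputError(f"K mismatch: {reference.K} != {target.K}")
    shared = [g for g in reference.gene_ids if g in target._row_index]
    if not shared:
        raise InputError("partitions share no genes")
    ref_cols = np.array([reference._row_index[g] for g in shared])
    tgt_cols = np.array([target._row_index[g] for g in shared])
    R = reference.membership[:, ref_cols].astype(np.int64)
    T = target.membership[:, tgt_cols].astype(np.int64)
    inter = R @ T.T
    cost = R.sum(axis=1)[:, None] + T.sum(axis=1)[None, :] - 2 * inter
    perm = _minmin_matching(cost)
    M = target.membership[perm]
    ref_id = "{}|{}|K={}".format(*reference.source)
    return Partition(
        K=target.K,
        gene_ids=list(target.gene_ids),
        membership=M,
        source=target.source,
        relabelled_to=ref_id,
    )


def build_copam(partitions: list[Partition], collection: DatasetCollection) -> CoPaM:
    """Average relabelled partitions into a fuzzy CoPaM, weighting by presence.

    Each gene's fuzzy memberships are averaged over exactly those partitions
    whose dataset contains the gene, so genes measured in only ``L*`` of the
    ``L`` datasets still obtain a full-weight consensus membership.
    """
    if not partitions:
        raise InputError("no partitions to average")
    K = partitions[0].K
    if any(p.K != K for p in partitions):
        raise InputError("all partitions must share K")
    unaligned = [p for p in partitions if p.relabelled_to is None]
    ref_ids = {p.relabelled_to for p in partitions if p.relabelled_to is not None}
    # the reference itself is allowed in unaligned form only if it is the single common reference
    if len(ref_ids) > 1:
        raise UsageError("partitions relabelled against different references")
    if len(unaligned) > 1:
        raise UsageError("partitions must be min-min relabelled against a common reference")
    G = collection.n_genes
    sums = np.zeros((K, G))
    counts = np.zeros(G, dtype=int)
    for p in partitions:
        cols_p, cols_u = [], []
        for u, g in enumerate(collection.gene_universe):
            j = p._row_index.get(g)
            if j is not None:
                cols_p.append(j)
                cols_u.append(u)
        cols_p = np.asarray(cols_p, dtype=int)
        cols_u = np.asarray(cols_u, dtype=int)
        sums[:, cols_u] += p.membership[:, cols_p]
        counts[cols_u] += 1
    fuzzy = np.zeros_like(sums)
    pos = counts > 0
    fuzzy[:, pos] = sums[:, pos] / counts[pos]
    return CoPaM(K=K, gene_ids=list(collection.gene_universe), fuzzy=fuzzy, support=counts)


def dtb_binarise(copam: CoPaM, params: DTBParams | float = 0.0) -> np.ndarray:
    """Difference-threshold binarisation of a CoPaM into a K x G binary matrix.

    Gene ``g`` is assigned to its argmax cluster iff the winning membership
    exceeds every other cluster's membership by at least ``delta``; otherwise
    the column stays all-zero (unassigned).  At ``delta = 0`` a strict unique
    maximum is required, so exact ties are unassigned.
    """
    if not isinstance(params, DTBParams):
        params = DTBParams(float(params))
    F = copam.fuzzy
    K, G = F.shape
    out = np.zeros((K, G), dtype=np.uint8)
    if G == 0:
        return out
    top = np.argmax(F, axis=0)
    m1 = F[top, np.arange(G)]
    F2 = F.copy()
    F2[top, np.arange(G)] = -np.inf
    m2 = F2.max(axis=0) if K > 1 else np.full(G, -np.inf)
    margin = m1 - m2
    assigned = margin >= params.delta if params.delta > 0 else margin > 0
    assigned &= copam.support > 0
    out[top[assigned], np.nonzero(assigned)[0]] = 1
    return out


# ---------------------------------------------------------------------------
# Full type-A consensus runs


def _method_partitions(name, data, K, gene_ids, dataset_id, seed,
                       pdist_cache=None, linkage_cache=None) -> Partition:
    if name == "kmeans_ka":
        labels = KaufmanKMeans(n_clusters=K, pairwise_distances=pdist_cache).fit_predict(data)
        method = "kmeans_ka"
    elif name == "som":
        labels = BubbleSOM(n_clusters=K, random_state=seed).fit_predict(data)
        method = f"som[seed={seed}]"
    elif name == "hc_ward":
        labels = WardClustering(n_clusters=K, linkage_matrix=linkage_cache).fit_predict(data)
        method = "hc_ward"
    else:
        raise InputError(f"unknown clustering method {name!r}")
    return Partition.from_labels(labels, gene_ids, K, source=(method, dataset_id, K))


class UnclesTypeA(BaseEstimator):
    """Type-A consensus clustering across a collection of datasets.

    For each ``K`` in ``k_values`` the estimator clusters every dataset with
    every method (``R = C x L`` partitions), min-min relabels all partitions
    against the first one, averages them into a CoPaM with missing-gene
    weighting, and binarises at every ``delta`` in ``deltas``.  Every
    non-empty binarised cluster becomes a candidate tagged with its
    provenance ``(K, delta, cluster index)``.

    Fitted attributes:

    ``candidates_`` : list of :class:`~uncles.selection.ClusterCandidate`
    ``copams_`` : dict mapping K -> :class:`CoPaM`
    """

    def __init__(self, k_values=DEFAULT_K_VALUES, deltas=DEFAULT_DELTAS,
                 methods=DEFAULT_METHODS, random_state: int = 0):
        self.k_values = k_values
        self.deltas = deltas
        self.methods = methods
        self.random_state = random_state

    def fit(self, collection: DatasetCollection, y=None):
        from .selection import ClusterCandidate, cluster_mse

        if not self.methods:
            raise InputError("at least one clustering method required")
        k_values = [int(k) for k in (self.k_values if np.iterable(self.k_values) else [self.k_values])]
        deltas = [float(d) for d in self.deltas]

        # per-dataset caches shared across K: pairwise distances (k-means
        # seeding) and the Ward tree (cut at each K)
        pdists, linkages = [], []
        need_pdist = "kmeans_ka" in self.methods
        need_link = "hc_ward" in self.methods
        for ds in collection.datasets:
            pdists.append(cdist(ds.values, ds.values) if need_pdist else None)
            linkages.append(linkage(ds.values, method="ward") if need_link else None)

        candidates: list[ClusterCandidate] = []
        copams: dict[int, CoPaM] = {}
        for K in k_values:
            partitions = []
            for l, ds in enumerate(collection.datasets):
                for m, name in enumerate(self.methods):
                    seed = self.random_state * 100003 + K * 1009 + l * 31 + m
                    partitions.append(
                        _method_partitions(
                            name, ds.values, K, ds.gene_ids, ds.dataset_id,
                            seed % (2**31 - 1), pdists[l], linkages[l],
                        )
                    )
            reference = partitions[0]
            aligned = [reference] + [relabel_min_min(reference, p) for p in partitions[1:]]
            copam = build_copam(aligned, collection)
            copams[K] = copam
            genes = np.asarray(collection.gene_universe)
            for d in deltas:
                B = dtb_binarise(copam, DTBParams(d))
                for k in range(K):
                    members = genes[B[k].astype(bool)]
                    if members.size:
                        mse = cluster_mse(members, collection)
                        candidates.append(
                            ClusterCandidate(
                                genes=tuple(sorted(members)), K=K, delta=d,
                                index=k, mse=mse,
                            )
                        )
            logger.info("K=%d: %d partitions -> %d candidates so far",
                        K, len(partitions), len(candidates))
        self.candidates_ = candidates
        self.copams_ = copams
        return self


def uncles_type_a(collection: DatasetCollection, K, methods=DEFAULT_METHODS,
                  delta_grid=DEFAULT_DELTAS, random_state: int = 0):
    """Run the type-A consensus for one K (or a list of K values).

    Returns the list of non-empty binarised cluster candidates over the whole
    ``(K, delta)`` grid.
    """
    ks = K if np.iterable(K) else [K]
    est = UnclesTypeA(k_values=ks, deltas=delta_grid, methods=methods,
                      random_state=random_state)
    return est.fit(collection).candidates_
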