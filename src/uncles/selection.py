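"""M-N scatter-plot cluster selection.

Every candidate cluster from the ``(K, delta)`` grid is a point on a plane
whose horizontal axis is dispersion (a per-dataset, per-dimension normalised
mean-square error) and whose vertical axis is ``log10`` of the cluster size.
Good clusters are large and tight, i.e. near the top-left corner.  Selection
is greedy: pick the candidate closest to the corner, discard every candidate
overlapping it, recompute the plot's axes over the survivors, and repeat.
Selected gene sets are therefore pairwise disjoint and come out ordered from
best to worst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DatasetCollection
from .errors import InputError

__all__ = [
    "ClusterCandidate",
    "MNSelection",
    "cluster_mse",
    "matrix_mse",
    "mn_distances",
    "select_clusters",
]


@dataclass(frozen=True)
class ClusterCandidate:
    """A candidate gene set with provenance ``(K, delta, cluster index)`` and MSE."""

    genes: tuple[str, ...]
    K: int
    delta: float
    index: int
    mse: float

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise InputError("a candidate cluster must contain at least one gene")
        if not np.isfinite(self.mse) or self.mse < 0:
            raise InputError("candidate MSE must be finite and non-negative")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)

    @property
    def provenance(self) -> tuple[int, float, int]:
        return (self.K, self.delta, self.index)


@dataclass
class MNSelection:
    """Ordered result of greedy M-N selection: candidates with their distances."""

    selected: list[tuple[ClusterCandidate, float]] = field(default_factory=list)

    @property
    def candidates(self) -> list[ClusterCandidate]:
        return [c for c, _ in self.selected]

    @property
    def distances(self) -> list[float]:
        return [d for _, d in self.selected]

    def __len__(self) -> int:
        return len(self.selected)

    def __iter__(self):
        return iter(self.selected)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rank": i + 1, "distance": d, "K": c.K, "delta": c.delta,
             "index": c.index, "size": c.size, "mse": c.mse}
            for i, (c, d) in enumerate(self.selected)
        ]
        return pd.DataFrame(rows)


def matrix_mse(X: np.ndarray) -> float:
    """Dispersion of a genes x conditions block around its mean profile.

    ``(1 / (n * D)) * sum_g ||x_g - mean profile||^2``; a single row gives 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise InputError("matrix_mse expects a non-empty 2-D block")
    centred = X - X.mean(axis=0, keepdims=True)
    return float((centred ** 2).sum() / (X.shape[0] * X.shape[1]))


def cluster_mse(gene_set, collection: DatasetCollection) -> float:
    """Mean over datasets of the per-dataset dispersion of the gene set.

    In each dataset only the subset of genes actually measured there
    contributes; datasets containing none of the genes are skipped.
    """
    genes = list(gene_set)
    if not genes:
        raise InputError("empty gene set")
    per_dataset = []
    for ds in collection.datasets:
        rows = ds.rows_of(genes)
        if rows.size:
            per_dataset.append(matrix_mse(ds.values[rows]))
    if not per_dataset:
        raise InputError("gene set absent from every dataset")
    return float(np.mean(per_dataset))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:  # degenerate spread collapses the axis to 0
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def mn_distances(candidates: list[ClusterCandidate]) -> np.ndarray:
    """Distance of each candidate from the top-left corner of the M-N plot.

    MSE and ``log10(size)`` are min-max normalised to [0, 1] over the supplied
    candidates; the corner is (0 dispersion, maximal size).
    """
    if not candidates:
        raise InputError("no candidates")
    mse = np.array([c.mse for c in candidates], dtype=float)
    logsize = np.log10([c.size for c in candidates])
    m = _minmax(mse)  # degenerate spread -> 0 contribution
    if logsize.max() == logsize.min():
        s_term = np.zeros_like(logsize)  # degenerate size axis contributes 0 too
    else:
        s_term = 1.0 - _minmax(logsize)
    return np.sqrt(m ** 2 + s_term ** 2)


def _pick(candidates: list[ClusterCandidate], dists: np.ndarray) -> int:
    """Index of the minimum-distance candidate; ties prefer larger size, then
    lower (K, delta, index) provenance."""
    best = None
    best_key = None
    for i, (c, d) in enumerate(zip(candidates, dists)):
        key = (d, -c.size, c.K, c.delta, c.index)
        if best_key is None or key < best_key:
            best, best_key = i, key
    return best


def select_clusters(candidates: list[ClusterCandidate],
                    max_clusters: int | None = None) -> MNSelection:
    """Greedy M-N selection with overlap removal.

    Each round recomputes the distances over the remaining candidates, selects
    the closest-to-corner candidate, and removes it together with every
    candidate sharing at least one gene with it.  Stops when ``max_clusters``
    are selected or the plot is empty.
    """
    if not candidates:
        raise InputError("no candidates to select from")
    remaining = list(candidates)
    result = MNSelection()
    while remaining and (max_clusters is None or len(result) < max_clusters):
        dists = mn_distances(remaining)
        i = _pick(remaining, dists)
        winner = remaining[i]
        result.selected.append((winner, float(dists[i])))
        wset = winner.gene_set
        remaining = [c for c in remaining if not (c.gene_set & wset)]
    return result
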