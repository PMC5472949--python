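"""Core containers: per-dataset expression matrices and multi-dataset collections.

An :class:`ExpressionDataset` holds one genes x conditions matrix together with
its platform kind (one-colour intensities or two-colour log-ratios), which
decides how it is normalised.  A :class:`DatasetCollection` gathers ``L`` such
datasets over a shared gene universe with a gene x dataset presence mask and
the inclusion threshold ``L*`` (``min_presence``): a gene enters the analysis
only if it is measured in at least ``L*`` of the ``L`` datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

ONE_COLOUR = "one_colour"
TWO_COLOUR = "two_colour"
PLATFORM_KINDS = (ONE_COLOUR, TWO_COLOUR)


def canonical_gene_id(gene_id: str) -> str:
    """Normalise a gene identifier: trim whitespace, compare case-insensitively."""
    return str(gene_id).strip().upper()


@dataclass
class ExpressionDataset:
    """One expression matrix (genes x conditions) with platform metadata."""

    dataset_id: str
    gene_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray
    platform_kind: str = ONE_COLOUR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [canonical_gene_id(g) for g in self.gene_ids]
        self.condition_labels = [str(c) for c in self.condition_labels]
        if self.values.ndim != 2:
            raise InputError(f"{self.dataset_id}: expression matrix must be 2-D")
        n_genes, n_cond = self.values.shape
        if n_cond < 1:
            raise InputError(f"{self.dataset_id}: at least one condition required")
        if len(self.gene_ids) != n_genes:
            raise InputError(f"{self.dataset_id}: {len(self.gene_ids)} gene ids for {n_genes} rows")
        if len(self.condition_labels) != n_cond:
            raise InputError(f"{self.dataset_id}: condition label count mismatch")
        if len(set(self.gene_ids)) != n_genes:
            raise InputError(f"{self.dataset_id}: duplicate gene ids after summarisation")
        if self.platform_kind not in PLATFORM_KINDS:
            raise InputError(f"{self.dataset_id}: unknown platform kind {self.platform_kind!r}")
        if np.isnan(self.values).any():
            raise InputError(f"{self.dataset_id}: missing cells are not allowed")
        self._row_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return canonical_gene_id(gene_id) in self._row_index

    def row_of(self, gene_id: str) -> int:
        return self._row_index[canonical_gene_id(gene_id)]

    def rows_of(self, gene_ids) -> np.ndarray:
        """Row indices of the genes present in this dataset (absent genes skipped)."""
        idx = self._row_index
        return np.array(
            [idx[c] for c in (canonical_gene_id(g) for g in gene_ids) if c in idx],
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_labels)


@dataclass
class DatasetCollection:
    """``L`` datasets over a shared gene universe with presence mask and ``L*``.

    ``presence_mask[i, l]`` is True when ``gene_universe[i]`` is measured in
    dataset ``l``; every row sums to at least ``min_presence``.
    """

    datasets: list[ExpressionDataset]
    gene_universe: list[str]
    presence_mask: np.ndarray
    min_presence: int
    _universe_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.presence_mask = np.asarray(self.presence_mask, dtype=bool)
        G, L = len(self.gene_universe), len(self.datasets)
        if self.presence_mask.shape != (G, L):
            raise InputError(
                f"presence mask shape {self.presence_mask.shape} != ({G}, {L})"
            )
        if self.min_presence > L:
            raise InputError(f"min_presence {self.min_presence} exceeds L={L}")
        counts = self.presence_mask.sum(axis=1)
        if G and counts.min() < self.min_presence:
            raise InputError("a universe gene is present in fewer than min_presence datasets")
        for l, ds in enumerate(self.datasets):
            members = set(ds.gene_ids)
            claimed = {g for g, p in zip(self.gene_universe, self.presence_mask[:, l]) if p}
            missing = claimed - members
            if missing:
                raise InputError(
                    f"presence mask claims {sorted(missing)[:3]}... in {ds.dataset_id} but absent"
                )
        self._universe_index = {g: i for i, g in enumerate(self.gene_universe)}

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def n_genes(self) -> int:
        return len(self.gene_universe)

    def universe_index(self, gene_id: str) -> int:
        return self._universe_index[canonical_gene_id(gene_id)]
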