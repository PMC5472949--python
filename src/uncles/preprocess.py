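"""Per-dataset pre-processing: quantile normalisation, replicate medians,
representative-probe selection, per-gene standardisation, and assembly of a
multi-dataset collection under the ``L*`` presence threshold.

Conventions fixed here and used throughout the package:

* standard deviations use the population (denominator ``n``) convention;
* quantile-normalisation ties receive the mean of the cross-column rank means
  they span, so the transform is deterministic and rank-preserving;
* gene identifiers are compared case-insensitively after trimming whitespace;
* missing cells are rejected rather than imputed — the unit of missingness in
  this framework is a whole gene per dataset, not a cell.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datasets import (
    ONE_COLOUR,
    DatasetCollection,
    ExpressionDataset,
    canonical_gene_id,
)
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_normalise",
    "summarise_replicates",
    "select_representative_probe",
    "collapse_probes",
    "normalise_dataset",
    "build_collection",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_presence_mask",
]


def quantile_normalise(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalise the columns of a genes x samples matrix.

    After the transform every column holds the identical multiset of values —
    the per-rank cross-column means — while each column's internal rank order
    is preserved.  Tied values within a column are given the mean of the rank
    means their positions span.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InputError("quantile_normalise expects a 2-D matrix with >= 1 column")
    if np.isnan(X).any():
        raise InputError("missing cells are not allowed in quantile normalisation")
    rank_means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # walk runs of ties in sorted order; a run spanning sorted positions
        # [a, b) receives mean(rank_means[a:b])
        assigned = np.empty(n)
        a = 0
        while a < n:
            b = a + 1
            while b < n and sorted_col[b] == sorted_col[a]:
                b += 1
            assigned[a:b] = rank_means[a:b].mean()
            a = b
        out[order, j] = assigned
    return out


def summarise_replicates(matrix: np.ndarray, replicate_map: dict[str, list[int]]) -> np.ndarray:
    """Collapse replicate sample columns to one column per condition (median).

    ``replicate_map`` maps each condition label to the sample column indices
    belonging to it; every sample must be assigned to exactly one condition.
    Output column order follows the mapping's insertion order.
    """
    X = np.asarray(matrix, dtype=float)
    if not replicate_map:
        raise InputError("replicate map is empty")
    seen: set[int] = set()
    for cond, idxs in replicate_map.items():
        if len(idxs) == 0:
            raise InputError(f"condition {cond!r} has no replicate samples")
        dup = seen.intersection(idxs)
        if dup:
            raise InputError(f"samples {sorted(dup)} assigned to more than one condition")
        seen.update(idxs)
    if seen != set(range(X.shape[1])):
        raise InputError("every sample must be assigned to exactly one condition")
    cols = [np.median(X[:, idxs], axis=1) for idxs in replicate_map.values()]
    return np.column_stack(cols)


def _coefficient_of_variation(row: np.ndarray) -> float:
    sd = float(np.std(row))  # population convention
    mean = float(np.mean(row))
    if mean == 0.0:
        return np.inf if sd > 0 else -np.inf  # -inf marks the excluded all-constant case
    return sd / abs(mean)


def select_representative_probe(probe_rows: np.ndarray, q1: float) -> int:
    """Pick the representative probe for a gene measured by several probes.

    Among probes whose expression exceeds ``q1`` (the dataset-wide first
    quartile) in at least 25% of samples, the probe with the largest
    coefficient of variation (population sd / |mean|) wins; if none qualifies,
    the max-CV probe overall is returned.  Zero-mean probes with positive sd
    count as infinitely variable; all-constant zero-mean probes are excluded.
    """
    P = np.atleast_2d(np.asarray(probe_rows, dtype=float))
    if P.shape[0] < 1:
        raise InputError("at least one probe row required")
    cv = np.array([_coefficient_of_variation(P[i]) for i in range(P.shape[0])])
    frac_above = (P > q1).mean(axis=1)
    qualifies = frac_above >= 0.25
    pool = np.where(qualifies & (cv > -np.inf))[0]
    if pool.size == 0:
        pool = np.where(cv > -np.inf)[0]
    if pool.size == 0:
        warnings.warn("all probes constant at zero; returning lowest index", stacklevel=2)
        return 0
    return int(pool[np.argmax(cv[pool])])


def collapse_probes(
    values: np.ndarray,
    probe_ids: list[str],
    probe_to_gene: dict[str, str],
) -> tuple[list[str], np.ndarray]:
    """Reduce a probe x sample matrix to one representative row per gene.

    Probes without a mapping are dropped.  ``q1`` is the first quartile of all
    expression values in the dataset, shared by every gene's selection.
    """
    X = np.asarray(values, dtype=float)
    q1 = float(np.percentile(X, 25))
    gene_rows: dict[str, list[int]] = {}
    mapping = {canonical_gene_id(p): canonical_gene_id(g) for p, g in probe_to_gene.items()}
    for i, probe in enumerate(probe_ids):
        gene = mapping.get(canonical_gene_id(probe))
        if gene is not None:
            gene_rows.setdefault(gene, []).append(i)
    if not gene_rows:
        raise InputError("no probe maps to a gene")
    genes, rows = [], []
    for gene, idxs in gene_rows.items():
        best = select_representative_probe(X[idxs], q1)
        genes.append(gene)
        rows.append(X[idxs[best]])
    return genes, np.vstack(rows)


def normalise_dataset(ds: ExpressionDataset) -> ExpressionDataset:
    """Normalise one dataset according to its platform kind.

    One-colour intensities are quantile-normalised column-wise, then each
    gene's profile is shifted and scaled to zero mean and unit (population)
    standard deviation.  Two-colour log-ratios are only zero-centred per gene.
    Constant one-colour rows cannot be scaled; they are set to all zeros and
    logged.
    """
    X = ds.values
    if ds.platform_kind == ONE_COLOUR:
        X = quantile_normalise(X)
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        flat = sd[:, 0] == 0
        sd[flat] = 1.0
        X = (X - mean) / sd
        if flat.any():
            X[flat] = 0.0
            flagged = [ds.gene_ids[i] for i in np.where(flat)[0]]
            logger.warning(
                "%s: %d constant gene(s) set to zero (cannot scale to unit sd): %s",
                ds.dataset_id, len(flagged), flagged[:5],
            )
    else:  # two-colour log-ratios: centre only
        X = X - X.mean(axis=1, keepdims=True)
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        gene_ids=list(ds.gene_ids),
        condition_labels=list(ds.condition_labels),
        values=X,
        platform_kind=ds.platform_kind,
    )


def build_collection(datasets: list[ExpressionDataset], min_presence: int) -> DatasetCollection:
    """Assemble a :class:`DatasetCollection` keeping genes present in >= ``L*`` datasets."""
    L = len(datasets)
    if L == 0:
        raise InputError("no datasets")
    if min_presence > L:
        raise InputError(f"min_presence {min_presence} exceeds number of datasets {L}")
    counts: dict[str, int] = {}
    order: list[str] = []
    for ds in datasets:
        for g in ds.gene_ids:
            if g not in counts:
                counts[g] = 0
                order.append(g)
            counts[g] += 1
    universe = [g for g in order if counts[g] >= min_presence]
    dropped = len(order) - len(universe)
    if dropped:
        logger.info("dropped %d gene(s) present in fewer than %d datasets", dropped, min_presence)
    if not universe:
        raise InputError("no gene satisfies the presence threshold")
    mask = np.zeros((len(universe), L), dtype=bool)
    for l, ds in enumerate(datasets):
        members = set(ds.gene_ids)
        for i, g in enumerate(universe):
            mask[i, l] = g in members
    return DatasetCollection(
        datasets=list(datasets),
        gene_universe=universe,
        presence_mask=mask,
        min_presence=min_presence,
    )


# ---------------------------------------------------------------------------
# TSV input / output

def read_expression_tsv(path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a TSV expression matrix (row 1 = sample labels, column 1 = gene id)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # surface the offending file to the user
        raise InputError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise InputError(f"{path}: no sample columns")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise InputError(
            f"{path}: missing/non-numeric cell at gene {df.index[i]!r} (row {i + 2}), "
            f"column {df.columns[j]!r}"
        )
    return [str(g) for g in df.index], [str(c) for c in df.columns], values


def write_expression_tsv(path, gene_ids, condition_labels, values) -> None:
    df = pd.DataFrame(values, index=gene_ids, columns=condition_labels)
    df.to_csv(path, sep="\t", float_format="%.6g", index_label="gene")


def write_presence_mask(path, collection: DatasetCollection) -> None:
    df = pd.DataFrame(
        collection.presence_mask.astype(int),
        index=collection.gene_universe,
        columns=[ds.dataset_id for ds in collection.datasets],
    )
    df.to_csv(path, sep="\t", index_label="gene")
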