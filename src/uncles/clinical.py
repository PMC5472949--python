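"""Signature-level statistics on clinical cohorts.

Implements the downstream prognosis toolkit: hypoxia scores (rank-scaled
per-sample signature medians), univariate Cox proportional-hazards ratios,
time-horizon ROC/AUC via the Mann-Whitney statistic, per-gene and
signature-level ER-status ANOVA with fold-changes, the random-cluster
tightness test, Spearman-correlation sub-cluster discovery, and
inter-signature correlation matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .datasets import ExpressionDataset
from .errors import ConfigurationError, FitError, InputError
from .selection import matrix_mse

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalCohort",
    "HypoxiaScore",
    "CoxResult",
    "select_clinical_probeset",
    "hypoxia_score",
    "cox_hr",
    "roc_auc",
    "er_anova",
    "signature_er_test",
    "tightness_test",
    "subcluster_discovery",
    "signature_correlations",
    "cluster_profile_correlation",
    "read_clinical_tsv",
]


@dataclass
class ClinicalCohort:
    """Expression plus survival and ER metadata, sample-aligned.

    ``expression`` is genes x samples on a positive (quantile-normalised or
    intensity-like) scale; ``os_time`` strictly positive overall-survival
    times in years; ``os_event`` 1 = death observed, 0 = censored;
    ``er_status`` ``"positive"``/``"negative"`` (NaN where missing).
    """

    expression: pd.DataFrame
    os_time: pd.Series
    os_event: pd.Series
    er_status: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.expression.columns)
        for name, s in (("os_time", self.os_time), ("os_event", self.os_event),
                        ("er_status", self.er_status)):
            if list(s.index) != samples:
                raise ConfigurationError(f"{name} index must match expression columns")
        if (self.os_time <= 0).any():
            raise ConfigurationError("survival times must be strictly positive")
        if not self.os_event.isin([0, 1]).all():
            raise ConfigurationError("event indicator must be binary")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def standardised(self) -> pd.DataFrame:
        """Per-gene zero-mean unit-(population)-sd expression; constant rows -> 0."""
        X = self.expression.to_numpy(dtype=float)
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        flat = sd[:, 0] == 0
        sd[flat] = 1.0
        Z = (X - mean) / sd
        Z[flat] = 0.0
        return pd.DataFrame(Z, index=self.expression.index, columns=self.expression.columns)


@dataclass
class HypoxiaScore:
    """Per-sample summary of a signature: rank-scaled median expression in [0, 1]."""

    signature_id: str
    scores: pd.Series


@dataclass
class CoxResult:
    """Univariate Cox fit of survival on a hypoxia score (full 0 -> 1 range)."""

    hazard_ratio: float
    p_value: float
    coefficient: float
    se: float

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise FitError("hazard ratio must be positive")


def select_clinical_probeset(probeset_rows: np.ndarray, q25: float) -> int:
    """Representative probe-set for a gene in a clinical dataset.

    The most variable probe-set (population variance) among those exceeding
    the dataset-wide 25th percentile in at least 25% of samples; if none
    qualifies, the most variable probe-set overall.
    """
    P = np.atleast_2d(np.asarray(probeset_rows, dtype=float))
    if P.shape[0] < 1:
        raise InputError("at least one probe-set required")
    var = P.var(axis=1)
    qualifies = (P > q25).mean(axis=1) >= 0.25
    pool = np.where(qualifies)[0]
    if pool.size == 0:
        pool = np.arange(P.shape[0])
    return int(pool[np.argmax(var[pool])])


def _present_genes(signature, expression: pd.DataFrame) -> list[str]:
    index = set(expression.index)
    return [g for g in signature if g in index]


def hypoxia_score(signature, cohort: ClinicalCohort, signature_id: str = "") -> HypoxiaScore:
    """Rank-scaled per-sample median of the signature genes.

    The per-sample median over the present signature genes is ranked across
    samples (average ranks on ties) and scaled as ``(rank - 1) / (n - 1)`` to
    [0, 1].  Being rank-based, the score is invariant to any strictly
    increasing transform of the expression values.
    """
    present = _present_genes(signature, cohort.expression)
    if not present:
        raise InputError("no signature gene present in the cohort")
    med = cohort.expression.loc[present].median(axis=0)
    n = len(med)
    if n < 2:
        scores = pd.Series(0.5, index=med.index)
    else:
        scores = pd.Series((stats.rankdata(med) - 1.0) / (n - 1.0), index=med.index)
    return HypoxiaScore(signature_id=signature_id or "signature", scores=scores)


def cox_hr(hs: HypoxiaScore, cohort: ClinicalCohort) -> CoxResult:
    """Univariate Cox proportional-hazards fit of survival on the score.

    Efron tie handling, Wald p-value; the hazard ratio is per full 0 -> 1
    range of the score.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if int(cohort.os_event.sum()) == 0:
        raise FitError("no events observed; Cox model cannot be fitted")
    if float(hs.scores.std()) == 0.0:
        raise FitError("score has no variation across samples")
    df = pd.DataFrame({
        "time": cohort.os_time.to_numpy(dtype=float),
        "event": cohort.os_event.to_numpy(dtype=int),
        "hs": hs.scores.to_numpy(dtype=float),
    })
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        raise FitError(f"Cox fit failed: {exc}") from exc
    beta = float(cph.params_["hs"])
    se = float(cph.standard_errors_["hs"])
    p = float(cph.summary.loc["hs", "p"])
    return CoxResult(hazard_ratio=float(np.exp(beta)), p_value=p, coefficient=beta, se=se)


def roc_auc(hs: HypoxiaScore, cohort: ClinicalCohort,
            horizon_years: float = 10.0) -> tuple[float, float]:
    """AUC of the score for death within a time horizon, with a p-value.

    Positives are samples whose event occurred within the horizon; samples
    surviving past the horizon (with or without a later event) are negatives;
    samples censored before the horizon carry no label and are excluded.  The
    AUC is the Mann-Whitney statistic of the score between the two classes and
    the p-value comes from the normal-approximated Mann-Whitney test.
    """
    t = cohort.os_time.to_numpy(dtype=float)
    e = cohort.os_event.to_numpy(dtype=int)
    s = hs.scores.to_numpy(dtype=float)
    pos = (e == 1) & (t <= horizon_years)
    neg = t > horizon_years
    if pos.sum() == 0 or neg.sum() == 0:
        raise InputError("both outcome classes must be present after horizon labelling")
    res = stats.mannwhitneyu(s[pos], s[neg], alternative="two-sided", method="asymptotic")
    auc = float(res.statistic) / (pos.sum() * neg.sum())
    return auc, float(res.pvalue)


def er_anova(cohort: ClinicalCohort, gene: str) -> tuple[float, float]:
    """Per-gene ER+/ER- differential expression.

    The p-value is a one-way two-group ANOVA on the standardised (zero-mean,
    unit-sd) expression; the fold-change is the ratio of ER+ to ER- group
    means on the unstandardised positive-scale expression.
    """
    er = cohort.er_status
    pos = (er == "positive").to_numpy()
    neg = (er == "negative").to_numpy()
    if pos.sum() == 0 or neg.sum() == 0:
        raise InputError("both ER classes must be present")
    raw = cohort.expression.loc[gene].to_numpy(dtype=float)
    z = raw - raw.mean()
    sd = z.std()
    if sd > 0:
        z = z / sd
    with np.errstate(invalid="ignore"):
        p = float(stats.f_oneway(z[pos], z[neg]).pvalue)
    if np.isnan(p):  # no within-group variance anywhere -> no evidence
        p = 1.0
    mean_neg = raw[neg].mean()
    fc = float(raw[pos].mean() / mean_neg) if mean_neg != 0 else np.inf
    return fc, p


def _er_anova_table(cohort: ClinicalCohort) -> pd.DataFrame:
    """Genome-wide per-gene (fold_change, p_value) table; computed vectorised."""
    er = cohort.er_status
    pos = (er == "positive").to_numpy()
    neg = (er == "negative").to_numpy()
    if pos.sum() == 0 or neg.sum() == 0:
        raise InputError("both ER classes must be present")
    X = cohort.expression.to_numpy(dtype=float)
    Z = cohort.standardised().to_numpy()
    n1, n2 = pos.sum(), neg.sum()
    m1, m2 = Z[:, pos].mean(axis=1), Z[:, neg].mean(axis=1)
    v1 = Z[:, pos].var(axis=1, ddof=1)
    v2 = Z[:, neg].var(axis=1, ddof=1)
    # two-group one-way ANOVA: F = MSbetween / MSwithin with (1, n-2) dof
    grand = Z.mean(axis=1)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = v1 * (n1 - 1) + v2 * (n2 - 1)
    dfw = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / dfw)
        p = stats.f.sf(F, 1, dfw)
    p = np.where(np.isfinite(p), p, 1.0)
    mean_neg = X[:, neg].mean(axis=1)
    with np.errstate(divide="ignore"):
        fc = X[:, pos].mean(axis=1) / mean_neg
    return pd.DataFrame({"fold_change": fc, "p_value": p}, index=cohort.expression.index)


@dataclass
class SignatureERResult:
    """Signature-level ER differential summary.

    ``fold_change`` is the geometric mean of the member genes' fold-changes.
    Significance compares member genes against all other genes by one-way
    ANOVA on two genome-wide per-gene summaries: ``log(-log p)`` of the
    per-gene ANOVA p-values and ``log(fold-change)``.  ``p_value`` is the
    fold-change-scale ANOVA p (the one paired with the fold-change);
    ``p_value_neglogp`` is the p-value-scale one.
    """

    fold_change: float
    p_value: float
    p_value_neglogp: float
    n_genes: int


def signature_er_test(signature, cohort: ClinicalCohort,
                      gene_table: pd.DataFrame | None = None) -> SignatureERResult:
    """Signature-level ER fold-change and significance versus the genome."""
    if gene_table is None:
        gene_table = _er_anova_table(cohort)
    present = _present_genes(signature, gene_table)
    if len(present) < 2:
        raise InputError("signature must have at least 2 genes present")
    member = gene_table.index.isin(set(present))
    if member.all():
        raise InputError("signature covers the whole genome; no background remains")
    log_fc = np.log(np.clip(gene_table["fold_change"].to_numpy(dtype=float), 1e-300, None))
    p = np.clip(gene_table["p_value"].to_numpy(dtype=float), 1e-300, 1.0)
    log_neglog_p = np.log(np.clip(-np.log(p), 1e-300, None))

    def _anova(x):
        a, b = x[member], x[~member]
        if np.allclose(a.var() + b.var(), 0.0) and np.isclose(a.mean(), b.mean()):
            return 1.0
        with np.errstate(invalid="ignore"):
            pv = float(stats.f_oneway(a, b).pvalue)
        return 1.0 if np.isnan(pv) else pv

    fc = float(np.exp(np.mean(np.log(
        np.clip(gene_table.loc[present, "fold_change"].to_numpy(dtype=float), 1e-300, None)
    ))))
    return SignatureERResult(
        fold_change=fc,
        p_value=_anova(log_fc),
        p_value_neglogp=_anova(log_neglog_p),
        n_genes=len(present),
    )


def tightness_test(gene_set, cohort: ClinicalCohort, n_random: int = 1000,
                   seed: int | None = None) -> tuple[float, float]:
    """Empirical tightness of a gene set against random same-size sets.

    The observed dispersion is the MSE of the standardised expression block;
    ``n_random`` random gene sets of the same size are drawn (without
    replacement within each set), a normal distribution is fitted to their
    MSEs, and the p-value is the lower-tail probability of the observed MSE
    or a more favourable (smaller) one.
    """
    genes = [g for g in gene_set]
    if len(genes) < 2:
        raise InputError("gene set must contain at least 2 genes")
    Z = cohort.standardised()
    present = _present_genes(genes, Z)
    if len(present) < 2:
        raise InputError("fewer than 2 genes of the set are present in the cohort")
    if len(present) > Z.shape[0]:
        raise InputError("gene set larger than the genome")
    observed = matrix_mse(Z.loc[present].to_numpy())
    rng = np.random.default_rng(seed)
    all_rows = Z.to_numpy()
    G = all_rows.shape[0]
    size = len(present)
    mses = np.empty(n_random)
    for r in range(n_random):
        idx = rng.choice(G, size=size, replace=False)
        mses[r] = matrix_mse(all_rows[idx])
    mu, sigma = float(mses.mean()), float(mses.std())
    if sigma == 0:
        return observed, float(observed <= mu)
    return observed, float(stats.norm.cdf((observed - mu) / sigma))


@dataclass
class SubclusterResult:
    subclusters: list[list[str]]
    correlation: pd.DataFrame
    order: list[str] = dc_field(default_factory=list)


def subcluster_discovery(gene_set, cohort: ClinicalCohort, linkage: str = "average",
                         cut: float = 0.6, n_clusters: int | None = None,
                         min_size: int = 5) -> SubclusterResult:
    """Split a gene set into tight sub-clusters by Spearman autocorrelation.

    The pairwise Spearman correlation over samples defines the distance
    ``1 - rho``; hierarchical clustering with the configured linkage is cut
    either at the distance threshold ``cut`` or into ``n_clusters`` groups.
    Sub-clusters smaller than ``min_size`` are dropped.  Constant gene rows
    (Spearman undefined) are excluded with a warning.  The returned
    correlation matrix is reordered by the dendrogram for heat-map output.
    """
    genes = _present_genes(gene_set, cohort.expression)
    if len(genes) < 3:
        raise InputError("need at least 3 genes present")
    X = cohort.expression.loc[genes].to_numpy(dtype=float)
    constant = X.std(axis=1) == 0
    if constant.any():
        dropped = [g for g, c in zip(genes, constant) if c]
        warnings.warn(f"excluding {len(dropped)} constant gene(s): {dropped[:5]}",
                      stacklevel=2)
        genes = [g for g, c in zip(genes, constant) if not c]
        X = X[~constant]
    if len(genes) < 3:
        raise InputError("fewer than 3 non-constant genes remain")
    rho = stats.spearmanr(X, axis=1).statistic
    rho = np.atleast_2d(rho)
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    groups: dict[int, list[str]] = {}
    for g, l in zip(genes, labels):
        groups.setdefault(int(l), []).append(g)
    subclusters = sorted(
        (sorted(m) for m in groups.values() if len(m) >= min_size),
        key=len, reverse=True,
    )
    order_idx = hierarchy.leaves_list(Z)
    ordered = [genes[i] for i in order_idx]
    corr = pd.DataFrame(rho, index=genes, columns=genes).loc[ordered, ordered]
    return SubclusterResult(subclusters=subclusters, correlation=corr, order=ordered)


def signature_correlations(signatures: dict[str, list[str]],
                           cohort: ClinicalCohort) -> pd.DataFrame:
    """Pairwise Spearman correlation between the signatures' hypoxia scores."""
    if len(signatures) < 2:
        raise InputError("need at least 2 signatures")
    names = list(signatures)
    hs = np.vstack([
        hypoxia_score(signatures[n], cohort, n).scores.to_numpy() for n in names
    ])
    rho = stats.spearmanr(hs, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=names, columns=names)


def cluster_profile_correlation(set_a, set_b, dataset: ExpressionDataset) -> float:
    """Pearson correlation between the two sets' mean condition-profiles.

    Returns NaN (with a warning) when either mean profile is constant.
    """
    rows_a = dataset.rows_of(set_a)
    rows_b = dataset.rows_of(set_b)
    if rows_a.size == 0 or rows_b.size == 0:
        raise InputError("both sets need at least one gene in the dataset")
    a = dataset.values[rows_a].mean(axis=0)
    b = dataset.values[rows_b].mean(axis=0)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant mean profile; correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def read_clinical_tsv(expression_path, metadata_path) -> ClinicalCohort:
    """Load a cohort from an expression TSV and a metadata TSV.

    Metadata columns: sample, os_time, os_event, er_status.
    """
    from .preprocess import read_expression_tsv

    genes, samples, values = read_expression_tsv(expression_path)
    expr = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"sample", "os_time", "os_event", "er_status"}
    if not required <= set(meta.columns):
        raise InputError(f"clinical metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample").reindex(samples)
    if meta["os_time"].isna().any():
        raise InputError("metadata does not cover every expression sample")
    return ClinicalCohort(
        expression=expr,
        os_time=meta["os_time"].astype(float),
        os_event=meta["os_event"].astype(int),
        er_status=meta["er_status"],
    )
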