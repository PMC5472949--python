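"""Synthetic multi-dataset expression collections and clinical cohorts.

The generator states a small, explicit world so every other module can be
tested without downloading anything:

* ``L`` heterogeneous one-colour datasets with 3-7 conditions each;
* planted clusters sharing, within each dataset, a common piecewise-linear
  monotone latent profile (time-series-like gradual up/down regulation) plus
  i.i.d. Gaussian noise; anti-correlated cluster pairs use negated profiles;
* background genes carrying independent unit-variance noise;
* per-dataset missing genes, every gene kept in at least ``L*`` datasets;
* clinical cohorts whose exponential survival hazard depends on signature
  scores, with uniform censoring and ER-status fold-change effects.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import binom, rankdata

from .clinical import ClinicalCohort
from .datasets import DatasetCollection, ExpressionDataset
from .errors import ConfigurationError
from .preprocess import build_collection, write_expression_tsv, write_presence_mask

__all__ = [
    "PlantedDesign",
    "ClinicalDesign",
    "ClinicalCohort",
    "generate_collection",
    "generate_clinical",
    "default_collection_design",
    "write_collection",
    "write_cohort",
]

PROFILE_KINDS = ("up", "down")


@dataclass
class PlantedDesign:
    """Specification of a planted multi-dataset collection.

    ``clusters`` is a list of ``(size, kind)`` pairs where ``kind`` is ``"up"``
    or ``"down"`` (monotone latent trajectory over each dataset's conditions).
    ``anticorrelated_pairs`` lists cluster index pairs whose latent profiles
    are exact negations of each other in every dataset.
    """

    n_genes: int = 2000
    n_datasets: int = 16
    samples_per_dataset: list[int] = dc_field(default_factory=list)
    clusters: list[tuple[int, str]] = dc_field(default_factory=lambda: [(120, "down"), (150, "up")])
    anticorrelated_pairs: list[tuple[int, int]] = dc_field(default_factory=lambda: [(0, 1)])
    noise_sd: float = 0.3
    min_presence: int = 13
    missing_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples_per_dataset:
            # heterogeneous condition counts cycling through the 3-7 range
            self.samples_per_dataset = [3 + (i % 5) for i in range(self.n_datasets)]
        if len(self.samples_per_dataset) != self.n_datasets:
            raise ConfigurationError("samples_per_dataset length must equal n_datasets")
        if any(s < 2 for s in self.samples_per_dataset):
            raise ConfigurationError("each dataset needs at least 2 conditions")
        if sum(s for s, _ in self.clusters) > self.n_genes:
            raise ConfigurationError("cluster sizes exceed n_genes")
        for s, kind in self.clusters:
            if s < 1 or kind not in PROFILE_KINDS:
                raise ConfigurationError(f"invalid cluster spec ({s}, {kind!r})")
        for i, j in self.anticorrelated_pairs:
            if not (0 <= i < len(self.clusters) and 0 <= j < len(self.clusters)) or i == j:
                raise ConfigurationError(f"invalid anticorrelated pair ({i}, {j})")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigurationError("missing_fraction must be in [0, 1)")
        if self.min_presence > self.n_datasets:
            raise ConfigurationError("min_presence exceeds n_datasets")
        # a gene's presence count is Binomial(L, 1 - missing_fraction); the
        # rejection sampler is hopeless if P(count >= L*) is negligible
        p_ok = binom.sf(self.min_presence - 1, self.n_datasets, 1 - self.missing_fraction)
        if p_ok < 1e-4:
            raise ConfigurationError(
                "missing_fraction incompatible with min_presence "
                f"(P(presence >= L*) = {p_ok:.2e})"
            )


def default_collection_design(seed: int = 0) -> PlantedDesign:
    """The stated world: L=16 datasets, L*=13, 2000 genes, two anti-correlated
    planted clusters of 120 and 150 genes, noise sd 0.3."""
    return PlantedDesign(seed=seed)


def _monotone_profile(rng: np.random.Generator, n_conditions: int, kind: str) -> np.ndarray:
    """Piecewise-linear monotone trajectory over conditions, range [-1, 1].

    Endpoints are pinned to -1 and 1 and a random interior breakpoint bends the
    slope, giving gradual, dataset-specific up/down regulation.
    """
    if n_conditions == 2:
        prof = np.array([-1.0, 1.0])
        rng.uniform()  # keep the stream aligned across condition counts
    else:
        t = np.linspace(0.0, 1.0, n_conditions)
        b = rng.uniform(0.25, 0.75)  # breakpoint position
        level = rng.uniform(-0.5, 0.5)  # value at the breakpoint
        prof = np.where(
            t <= b,
            -1.0 + (level + 1.0) * t / b,
            level + (1.0 - level) * (t - b) / (1.0 - b),
        )
    if kind == "down":
        prof = -prof
    return prof


def _presence_mask(rng: np.random.Generator, design: PlantedDesign) -> np.ndarray:
    """Per-gene uniform missingness, resampled until >= L* datasets remain."""
    G, L = design.n_genes, design.n_datasets
    mask = rng.random((G, L)) >= design.missing_fraction
    bad = np.where(mask.sum(axis=1) < design.min_presence)[0]
    tries = 0
    while bad.size:
        tries += 1
        if tries > 10000:
            raise ConfigurationError("presence-mask rejection sampling did not converge")
        mask[bad] = rng.random((bad.size, L)) >= design.missing_fraction
        bad = bad[mask[bad].sum(axis=1) < design.min_presence]
    return mask


def generate_collection(design: PlantedDesign) -> tuple[DatasetCollection, dict]:
    """Generate the planted collection plus a ground-truth dictionary.

    The truth dictionary records cluster memberships, per-(cluster, dataset)
    latent profiles and the presence mask, and is what tests assert against.
    """
    rng = np.random.default_rng(design.seed)
    G, L = design.n_genes, design.n_datasets
    gene_ids = [f"G{i:05d}" for i in range(G)]
    sizes = [s for s, _ in design.clusters]
    bounds = np.cumsum([0] + sizes)
    memberships = {
        c: gene_ids[bounds[c]: bounds[c + 1]] for c in range(len(design.clusters))
    }
    negated = {}
    for i, j in design.anticorrelated_pairs:
        negated[j] = i  # cluster j mirrors cluster i

    mask = _presence_mask(rng, design)

    profiles: dict[tuple[int, int], list[float]] = {}
    datasets = []
    for l in range(L):
        D = design.samples_per_dataset[l]
        base = {}
        for c, (size, kind) in enumerate(design.clusters):
            if c in negated:
                continue
            base[c] = _monotone_profile(rng, D, kind)
        for c in range(len(design.clusters)):
            prof = -base[negated[c]] if c in negated else base[c]
            profiles[(c, l)] = prof
        values = np.empty((G, D))
        for c in range(len(design.clusters)):
            lo, hi = bounds[c], bounds[c + 1]
            noise = rng.normal(0.0, design.noise_sd, (hi - lo, D)) if design.noise_sd > 0 else 0.0
            values[lo:hi] = profiles[(c, l)][None, :] + noise
        n_bg = G - bounds[-1]
        if n_bg:
            values[bounds[-1]:] = rng.normal(0.0, 1.0, (n_bg, D))
        values = values + 8.0  # intensity-like baseline; removed by standardisation
        present = np.where(mask[:, l])[0]
        datasets.append(
            ExpressionDataset(
                dataset_id=f"D{l + 1:02d}",
                gene_ids=[gene_ids[i] for i in present],
                condition_labels=[f"t{t}" for t in range(D)],
                values=values[present],
                platform_kind="one_colour",
            )
        )
    collection = build_collection(datasets, design.min_presence)
    truth = {
        "clusters": {str(c): genes for c, genes in memberships.items()},
        "anticorrelated_pairs": [list(p) for p in design.anticorrelated_pairs],
        "n_background": int(G - bounds[-1]),
        "universe_size": len(collection.gene_universe),
        "presence_mask": mask.astype(int).tolist(),
        "gene_ids": gene_ids,
        "profiles": {f"{c},{l}": list(map(float, p)) for (c, l), p in profiles.items()},
        "seed": design.seed,
    }
    return collection, truth


# ---------------------------------------------------------------------------
# Clinical cohorts


@dataclass
class ClinicalDesign:
    """Specification of a synthetic clinical cohort.

    ``signature_effects`` maps signature name -> log-hazard coefficient beta
    applied to that signature's realised hypoxia score (rank-scaled per-sample
    median, the same summary the downstream Cox fit uses).
    ``er_fold_changes`` maps signature name -> multiplicative ER+/ER- effect
    applied to member-gene expression on the positive scale.
    """

    n_samples: int = 500
    signature_effects: dict[str, float] = dc_field(default_factory=dict)
    er_fold_changes: dict[str, float] = dc_field(default_factory=dict)
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.05
    n_background_genes: int = 1000
    expression_noise_sd: float = 0.3
    tracking_amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("need at least 2 samples")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.n_background_genes < 0:
            raise ConfigurationError("n_background_genes must be non-negative")


def _rank_scale(values: np.ndarray) -> np.ndarray:
    """Average ranks scaled to [0, 1] via (rank - 1) / (n - 1)."""
    n = len(values)
    if n < 2:
        return np.full(n, 0.5)
    return (rankdata(values) - 1.0) / (n - 1.0)


def _calibrate_censoring_horizon(times: np.ndarray, rate: float) -> float:
    """Find tau so that uniform(0, tau) censoring yields ~``rate`` censored.

    For a fixed event time T and C ~ U(0, tau), P(censored) = min(T, tau)/tau;
    the expected censored fraction is monotone decreasing in tau, so bisect.
    """
    if rate == 0:
        return np.inf

    def frac(tau: float) -> float:
        return float(np.mean(np.minimum(times, tau) / tau))

    lo, hi = float(np.min(times)) * 1e-3, float(np.max(times)) * 10
    for _ in range(200):
        if frac(hi) <= rate:
            break
        hi *= 2
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_clinical(
    design: ClinicalDesign, signatures: dict[str, list[str]]
) -> tuple[ClinicalCohort, dict]:
    """Generate a clinical cohort with planted survival and ER effects.

    Expression is log-normal-like: each signature gene's log-expression tracks
    its signature's latent [0, 1] score with amplitude ``tracking_amplitude``
    plus Gaussian noise, so the per-sample signature median is monotone in the
    latent score.  Survival times are exponential with log-hazard
    ``sum_S beta_S * HS_S`` where ``HS_S`` is the realised rank-scaled median
    (the exact covariate the downstream Cox fit sees).  ER status is Bernoulli
    and signature fold-changes are planted multiplicatively on ER+ samples.
    """
    if not signatures:
        raise ConfigurationError("at least one signature required")
    for name, genes in signatures.items():
        if len(genes) == 0:
            raise ConfigurationError(f"signature {name!r} is empty")
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    latent = {name: rng.uniform(0.0, 1.0, n) for name in signatures}
    er = rng.random(n) < 0.5  # True = ER positive
    gene_order: list[str] = []
    membership: dict[str, list[str]] = {}
    for name, genes in signatures.items():
        membership[name] = list(genes)
        for g in genes:
            if g not in gene_order:
                gene_order.append(g)
    background = [f"BG{i:05d}" for i in range(design.n_background_genes)]
    all_genes = gene_order + background

    log_expr = np.empty((len(all_genes), n))
    for i, g in enumerate(all_genes):
        mu = rng.normal(6.0, 0.5)
        row = mu + rng.normal(0.0, design.expression_noise_sd, n)
        for name in signatures:
            if g in signatures[name]:
                row = row + design.tracking_amplitude * latent[name]
                fc = design.er_fold_changes.get(name, 1.0)
                if fc != 1.0:
                    row = row + np.log(fc) * er
        log_expr[i] = row
    expression = pd.DataFrame(np.exp(log_expr), index=all_genes, columns=samples)

    # realised hypoxia scores drive the hazard
    hs = {}
    for name, genes in signatures.items():
        med = expression.loc[genes].median(axis=0).to_numpy()
        hs[name] = _rank_scale(med)
    log_hazard = np.zeros(n)
    for name, beta in design.signature_effects.items():
        log_hazard += beta * hs[name]
    rate = design.baseline_hazard * np.exp(log_hazard)
    T = rng.exponential(1.0 / rate)
    T = np.maximum(T, 1e-6)
    tau = _calibrate_censoring_horizon(T, design.censoring_rate)
    if np.isfinite(tau):
        C = rng.uniform(0.0, tau, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)

    cohort = ClinicalCohort(
        expression=expression,
        os_time=pd.Series(time, index=samples, name="os_time"),
        os_event=pd.Series(event, index=samples, name="os_event"),
        er_status=pd.Series(np.where(er, "positive", "negative"), index=samples, name="er_status"),
    )
    truth = {
        "signatures": membership,
        "signature_effects": dict(design.signature_effects),
        "er_fold_changes": dict(design.er_fold_changes),
        "latent_scores": {k: v.tolist() for k, v in latent.items()},
        "hypoxia_scores": {k: v.tolist() for k, v in hs.items()},
        "seed": design.seed,
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# On-disk fixtures (TSV + truth JSON)


def write_collection(outdir, collection: DatasetCollection, truth: dict) -> None:
    """Write each dataset as TSV plus the presence mask and truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in collection.datasets:
        write_expression_tsv(outdir / f"{ds.dataset_id}.tsv", ds.gene_ids,
                             ds.condition_labels, ds.values)
    write_presence_mask(outdir / "presence_mask.tsv", collection)
    slim = {k: v for k, v in truth.items() if k not in ("presence_mask", "profiles")}
    (outdir / "truth.json").write_text(json.dumps(slim, indent=1))


def write_cohort(outdir, cohort: ClinicalCohort, truth: dict) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t",
                             float_format="%.6g", index_label="gene")
    meta = pd.DataFrame({
        "sample": cohort.os_time.index,
        "os_time": cohort.os_time.to_numpy(),
        "os_event": cohort.os_event.to_numpy(),
        "er_status": cohort.er_status.to_numpy(),
    })
    meta.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    slim = {k: v for k, v in truth.items() if k not in ("latent_scores", "hypoxia_scores")}
    (outdir / "truth.json").write_text(json.dumps(slim, indent=1))
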