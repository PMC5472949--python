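"""End-to-end pipeline orchestration behind the CLI.

A :class:`RunConfig` (typically parsed from YAML) names the input datasets (or
asks for a simulated collection), the consensus grid, and the output
directory.  :func:`run_pipeline` executes the stages in order — simulate /
load, preprocess, cluster, select, optionally enrich against gene lists —
writing every intermediate artefact plus a machine-readable JSON manifest with
seeds and output checksums.  Re-running with the same config and seed
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .consensus import DEFAULT_DELTAS, DEFAULT_K_VALUES, DEFAULT_METHODS, UnclesTypeA
from .datasets import ExpressionDataset
from .errors import ConfigurationError
from .gmt import read_gmt, write_gmt
from .preprocess import (
    build_collection,
    normalise_dataset,
    read_expression_tsv,
    summarise_replicates,
    write_expression_tsv,
    write_presence_mask,
)
from .selection import select_clusters
from .simulate import PlantedDesign, generate_collection, write_collection

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "uncles_run"
    seed: int = 0
    # either a simulation design...
    simulate: dict | None = None
    # ...or a manifest of dataset files: list of {path, platform_kind, replicate_map}
    datasets: list[dict] = field(default_factory=list)
    min_presence: int | None = None
    k_values: tuple = DEFAULT_K_VALUES
    deltas: tuple = DEFAULT_DELTAS
    methods: tuple = DEFAULT_METHODS
    max_clusters: int = 10
    enrich_lists: str | None = None  # GMT of target lists, optional

    def __post_init__(self) -> None:
        if self.simulate is None and not self.datasets:
            raise ConfigurationError("config must specify either 'simulate' or 'datasets'")
        if not self.k_values or not self.methods:
            raise ConfigurationError("k_values and methods must be non-empty")
        if any(not 0 <= d <= 1 for d in self.deltas):
            raise ConfigurationError("deltas must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_datasets(config: RunConfig) -> list[ExpressionDataset]:
    datasets = []
    for entry in config.datasets:
        genes, labels, values = read_expression_tsv(entry["path"])
        rep_map = entry.get("replicate_map")
        if rep_map:
            values = summarise_replicates(values, {c: list(idx) for c, idx in rep_map.items()})
            labels = list(rep_map)
        datasets.append(
            ExpressionDataset(
                dataset_id=entry.get("id", Path(entry["path"]).stem),
                gene_ids=genes,
                condition_labels=labels,
                values=values,
                platform_kind=entry.get("platform_kind", "one_colour"),
            )
        )
    return datasets


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": [], "outputs": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)

    try:
        # --- stage: obtain raw datasets -------------------------------------
        if config.simulate is not None:
            design = PlantedDesign(seed=config.seed, **config.simulate)
            collection_raw, truth = generate_collection(design)
            raw_dir = outdir / "simulated"
            write_collection(raw_dir, collection_raw, truth)
            record("simulate", *sorted(raw_dir.glob("*")))
            datasets = collection_raw.datasets
            min_presence = design.min_presence
        else:
            datasets = _load_datasets(config)
            min_presence = config.min_presence or len(datasets)
            manifest["stages"].append("load")

        # --- stage: preprocess ----------------------------------------------
        normalised = [normalise_dataset(ds) for ds in datasets]
        collection = build_collection(normalised, min_presence)
        norm_dir = outdir / "normalised"
        norm_dir.mkdir(exist_ok=True)
        for ds in collection.datasets:
            write_expression_tsv(norm_dir / f"{ds.dataset_id}.tsv", ds.gene_ids,
                                 ds.condition_labels, ds.values)
        write_presence_mask(norm_dir / "presence_mask.tsv", collection)
        record("preprocess", *sorted(norm_dir.glob("*")))

        # --- stage: consensus clustering over the (K, delta) grid ------------
        est = UnclesTypeA(k_values=config.k_values, deltas=config.deltas,
                          methods=config.methods, random_state=config.seed)
        est.fit(collection)
        cand_path = outdir / "candidates.tsv"
        with cand_path.open("w") as fh:
            fh.write("K\tdelta\tindex\tsize\tmse\tgenes\n")
            for c in est.candidates_:
                fh.write(f"{c.K}\t{c.delta}\t{c.index}\t{c.size}\t{c.mse:.6g}\t"
                         + ",".join(c.genes) + "\n")
        record("cluster", cand_path)

        # --- stage: M-N selection --------------------------------------------
        selection = select_clusters(est.candidates_, max_clusters=config.max_clusters)
        sel_path = outdir / "selection.tsv"
        selection.to_frame().to_csv(sel_path, sep="\t", index=False, float_format="%.6g")
        gmt_path = outdir / "selected_clusters.gmt"
        write_gmt(gmt_path, {
            f"C{i + 1}_K{c.K}_d{c.delta}": list(c.genes)
            for i, (c, _) in enumerate(selection)
        })
        record("select", sel_path, gmt_path)

        # --- stage: enrichment (optional) -------------------------------------
        if config.enrich_lists:
            from .enrichment import overlap_test

            lists = read_gmt(config.enrich_lists)
            rows = ["cluster\tlist\tN\tK\tn\tk\tp"]
            for i, (c, _) in enumerate(selection):
                for name, genes in lists.items():
                    r = overlap_test(c.genes, genes, collection.gene_universe)
                    rows.append(f"C{i + 1}\t{name}\t{r.universe_size}\t{r.list_size}"
                                f"\t{r.cluster_size}\t{r.overlap}\t{r.p_value:.6g}")
            enr_path = outdir / "enrichment.tsv"
            enr_path.write_text("\n".join(rows) + "\n")
            record("enrich", enr_path)
    except Exception:
        (outdir / "FAILED").write_text("\n".join(manifest["stages"]) + "\n")
        raise

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d stages, %d outputs",
                len(manifest["stages"]), len(manifest["outputs"]))
    return manifest
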