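"""One-command end-to-end co-occurrence analysis.

Stage order: read → prevalence filter → (Jaccard similarity) → rarefaction →
(Bray–Curtis) → SparCC → permutation p values → BH q values → positive
network → null-model clustering statistics → keystone ranking → reports.
All randomness derives from a single seed via named substreams, so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import network as net
from . import otu_table as ot
from .sparcc import (
    CorrelationResult,
    _qvals_from_pvals,
    permutation_pvalues,
    sparcc as _sparcc,
)

logger = logging.getLogger("cooccur")

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "RunReport",
    "validate_config",
    "run_pipeline",
]

# fixed substream indices: changing one stage's consumption never shifts another's
_SUBSTREAMS = {"rarefaction": 0, "dirichlet": 1, "permutation": 2, "null_graphs": 3}


def substream_seed(seed: int, name: str) -> int:
    """Derive an independent per-stage seed from the run seed."""
    idx = _SUBSTREAMS[name]
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis, with study defaults."""

    min_prevalence: int = 5
    rarefaction_depth: int = 2000
    n_estimation_iter: int = 20
    n_exclusion_iter: int = 10
    exclusion_threshold: float = 0.1
    n_permutations: int = 1000
    permutation_estimation_iter: int = 5
    fdr: float = 0.05
    r_min: float = 0.3
    positive_only: bool = True
    n_null_graphs: int = 1000
    jaccard_stage: str = "pre_rarefaction"  # or "post_rarefaction"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig | dict | None) -> PipelineConfig:
    """Fill defaults and reject out-of-range values with named errors."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(config) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = PipelineConfig(**config)
    if not (0.0 < config.fdr <= 1.0):
        raise ValueError(f"fdr must lie in (0, 1], got {config.fdr}")
    if not (-1.0 <= config.r_min <= 1.0):
        raise ValueError(f"r_min must lie in [-1, 1], got {config.r_min}")
    if config.min_prevalence < 1:
        raise ValueError("min_prevalence must be >= 1")
    if config.rarefaction_depth < 1:
        raise ValueError("rarefaction_depth must be >= 1")
    for name in ("n_estimation_iter", "n_permutations", "n_null_graphs",
                 "permutation_estimation_iter"):
        if getattr(config, name) < 1:
            raise ValueError(f"{name} must be >= 1")
    if config.n_exclusion_iter < 0:
        raise ValueError("n_exclusion_iter must be >= 0")
    if not (0.0 < config.exclusion_threshold < 1.0):
        raise ValueError("exclusion_threshold must lie in (0, 1)")
    if config.jaccard_stage not in ("pre_rarefaction", "post_rarefaction"):
        raise ValueError("jaccard_stage must be 'pre_rarefaction' or 'post_rarefaction'")
    if config.n_permutations < 1000:
        warnings.warn(
            f"n_permutations={config.n_permutations}: p-value resolution is "
            f"1/{config.n_permutations + 1}",
            stacklevel=2,
        )
    return config


@dataclass
class RunReport:
    """Config echo, per-stage record, network summary, artifact checksums."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    network: dict | None = None
    checksums: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=net._json_default)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_square_tsv(values: np.ndarray, ids: list[str], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t")


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and the partial outputs
    (if any) have been removed."""


def run_pipeline(table, config=None, out_dir=None) -> RunReport:
    """Run every stage of the co-occurrence analysis on one OTU table.

    Parameters
    ----------
    table : OTUTable or path
        Input count table (read as TSV when a path is given).
    config : PipelineConfig, dict or None
        Analysis parameters; missing keys take the study defaults.
    out_dir : path, optional
        When given, all artifacts (tables, matrices, edge list, GraphML,
        node stats, reports) are written beneath it and checksummed.

    Raises
    ------
    PipelineStageError
        If any stage fails; the message names the failing stage, and any
        partial artifacts already written are removed.
    """
    stage = {"name": "validate_config"}
    try:
        return _run_pipeline(table, config, out_dir, stage)
    except Exception as exc:
        if out_dir is not None:
            _cleanup_partial(Path(out_dir))
        raise PipelineStageError(
            f"pipeline stage '{stage['name']}' failed: {exc}"
        ) from exc


def _cleanup_partial(out: Path) -> None:
    if not out.exists():
        return
    for artifact in out.iterdir():
        if artifact.is_file():
            artifact.unlink()


def _run_pipeline(table, config, out_dir, stage) -> RunReport:
    cfg = validate_config(config)
    report = RunReport(config=cfg.to_dict())
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage["name"] = "read"
    if not isinstance(table, ot.OTUTable):
        table = ot.read_otu_table(table)
    report.add_stage("read", n_otus=table.n_otus, n_samples=table.n_samples)

    stage["name"] = "filter_prevalence"
    filtered = ot.filter_prevalence(table, cfg.min_prevalence)
    report.add_stage(
        "filter_prevalence",
        min_prevalence=cfg.min_prevalence,
        n_otus=filtered.n_otus,
        otus_removed=table.n_otus - filtered.n_otus,
    )

    stage["name"] = "jaccard"
    jaccard_pre = ot.jaccard_similarity_matrix(filtered)
    if cfg.jaccard_stage == "pre_rarefaction":
        median_jaccard = ot.median_pairwise(jaccard_pre)
        report.add_stage("jaccard", computed_on=cfg.jaccard_stage, median=median_jaccard)

    stage["name"] = "rarefy"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rarefied = ot.rarefy(filtered, cfg.rarefaction_depth,
                             seed=substream_seed(cfg.seed, "rarefaction"))
    report.add_stage(
        "rarefy",
        depth=cfg.rarefaction_depth,
        n_samples=rarefied.n_samples,
        samples_dropped=filtered.n_samples - rarefied.n_samples,
        warnings=[str(w.message) for w in caught],
    )

    if cfg.jaccard_stage == "post_rarefaction":
        median_jaccard = ot.median_pairwise(ot.jaccard_similarity_matrix(rarefied))
        report.add_stage("jaccard", computed_on=cfg.jaccard_stage, median=median_jaccard)

    stage["name"] = "bray_curtis"
    bray = ot.bray_curtis_matrix(rarefied)
    report.add_stage("bray_curtis", n_samples=rarefied.n_samples)

    stage["name"] = "sparcc"
    rho = _sparcc(
        rarefied,
        n_estimation_iter=cfg.n_estimation_iter,
        n_exclusion_iter=cfg.n_exclusion_iter,
        exclusion_threshold=cfg.exclusion_threshold,
        seed=substream_seed(cfg.seed, "dirichlet"),
    )
    pvals = permutation_pvalues(
        rarefied,
        rho,
        n_permutations=cfg.n_permutations,
        seed=substream_seed(cfg.seed, "permutation"),
        n_estimation_iter=cfg.permutation_estimation_iter,
        n_exclusion_iter=cfg.n_exclusion_iter,
        exclusion_threshold=cfg.exclusion_threshold,
    )
    result = CorrelationResult(
        list(rarefied.otu_ids),
        rho,
        pvals,
        _qvals_from_pvals(pvals),
        n_permutations=cfg.n_permutations,
        n_estimation_iter=cfg.n_estimation_iter,
        n_exclusion_iter=cfg.n_exclusion_iter,
        seed=cfg.seed,
    )
    report.add_stage(
        "sparcc",
        n_estimation_iter=cfg.n_estimation_iter,
        n_permutations=cfg.n_permutations,
        n_otus=len(result.otu_ids),
    )

    # shares both before and after rarefaction (the report carries both)
    share_pre = {o: ot.abundance_share(filtered, [o]) for o in filtered.otu_ids}
    share_post = {o: ot.abundance_share(rarefied, [o]) for o in rarefied.otu_ids}

    stage["name"] = "build_network"
    graph = net.build_network(
        result,
        abundance=share_post,
        taxonomy=rarefied.taxonomy,
        r_min=cfg.r_min,
        fdr=cfg.fdr,
        positive_only=cfg.positive_only,
    )
    report.add_stage(
        "build_network",
        r_min=cfg.r_min,
        fdr=cfg.fdr,
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
    )

    stage["name"] = "null_statistics"
    net_report = net.network_report(
        graph, n_null=cfg.n_null_graphs, seed=substream_seed(cfg.seed, "null_graphs")
    )
    report.add_stage(
        "null_statistics",
        n_null_graphs=cfg.n_null_graphs,
        clustering_ratio=net_report.clustering_ratio,
    )
    report.network = net_report.to_dict()
    report.network["median_jaccard"] = median_jaccard
    report.network["abundance_share_pre_rarefaction"] = share_pre
    report.network["abundance_share_post_rarefaction"] = share_post

    stage["name"] = "write_artifacts"
    if out is not None:
        ot.write_otu_table(filtered, out / "filtered_table.tsv")
        ot.write_otu_table(rarefied, out / "rarefied_table.tsv")
        bray.to_dataframe().to_csv(out / "bray_curtis.tsv", sep="\t")
        jaccard_pre.to_dataframe().to_csv(out / "jaccard_similarity.tsv", sep="\t")
        _write_square_tsv(result.rho, result.otu_ids, out / "correlations.tsv")
        _write_square_tsv(result.pvals, result.otu_ids, out / "pvalues.tsv")
        _write_square_tsv(result.qvals, result.otu_ids, out / "qvalues.tsv")
        result.pair_table().to_csv(out / "pairs.tsv", sep="\t", index=False)
        net.export_network(graph, out / "edges.tsv", format="edge_list_tsv")
        net.export_network(graph, out / "network.graphml", format="graphml")
        net_report.node_stats.rename_axis("otu_id").to_csv(out / "node_stats.tsv", sep="\t")
        net_report.to_json(out / "network_report.json")
        for artifact in sorted(out.iterdir()):
            if artifact.name != "run_report.json":
                report.checksums[artifact.name] = _sha256(artifact)
        report.to_json(out / "run_report.json")
        with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
            json.dump(report.checksums, fh, indent=2)
    return report
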