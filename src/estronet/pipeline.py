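"""End-to-end pipeline driver.

Runs the stages simulate (or load) -> filter -> profiles -> correlate ->
pcit -> network -> partition -> cluster [-> enrich] and persists every
stage output in the run directory as the TSV/GraphML formats the
individual modules define, plus a machine-readable ``run_summary.json``.
The pipeline is a pure function of (config, seed): rerunning an identical
configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import topology
from .deg_filter import GCNFilterConfig, GeneAnnotation, gcn_gene_filter, read_annotation
from .enrichment_validation import hypergeom_enrich, read_gmt
from .expression_io import (
    ExpressionMatrix,
    ProfileMatrix,
    log2fc_profiles,
    read_deg_table,
    read_expression,
    write_deg_table,
    write_expression,
    zscore_rows,
)
from .pcit_network import build_network, pcit_mask, pearson_profiles
from .profiles import choose_k, kmeans_profiles
from .synthetic_data import SyntheticDesign, simulate_dataset, write_truth

__all__ = ["PipelineConfig", "run_pipeline", "run_recovery"]

log = logging.getLogger("estronet.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.  See module docstring for the stages."""

    out_dir: str = "estronet_run"
    seed: int = 0

    # input: either simulate or load
    simulate: bool = True
    design: SyntheticDesign = field(default_factory=SyntheticDesign)
    expression_path: str | None = None
    metadata_path: str | None = None
    deg_path: str | None = None
    annotation_path: str | None = None

    # filter / network
    filter: GCNFilterConfig = field(default_factory=GCNFilterConfig)
    min_abs_r: float = 0.90
    threshold_mode: str = "abs"  # 'abs' (|r| > t) or 'r2' (r^2 > t)
    network_input: str = "log2fc"  # 'log2fc' or 'zscore'

    # clustering
    cluster_k: int = 5
    cluster_max_iter: int = 1000
    choose_k_range: tuple[int, int] | None = None

    # optional enrichment
    gmt_path: str | None = None

    # ---- YAML round-trip -------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "design" in raw and raw["design"] is not None:
            d = dict(raw["design"])
            for key in ("tissues", "days", "fc_jitter_range"):
                if key in d and d[key] is not None:
                    d[key] = tuple(d[key])
            if "module_sizes" in d and d["module_sizes"] is not None:
                d["module_sizes"] = dict(d["module_sizes"])
            raw["design"] = SyntheticDesign(**d)
        if "filter" in raw and raw["filter"] is not None:
            f = dict(raw["filter"])
            if "excluded_biotypes" in f:
                f["excluded_biotypes"] = frozenset(f["excluded_biotypes"])
            raw["filter"] = GCNFilterConfig(**f)
        if "choose_k_range" in raw and raw["choose_k_range"] is not None:
            raw["choose_k_range"] = tuple(raw["choose_k_range"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["filter"]["excluded_biotypes"] = sorted(raw["filter"]["excluded_biotypes"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("expression_path", "metadata_path", "deg_path"):
                if getattr(self, name) is None:
                    raise ValueError(
                        f"config field {name!r} is required when simulate is false"
                    )
        if self.threshold_mode not in ("abs", "r2"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.network_input not in ("log2fc", "zscore"):
            raise ValueError(f"unknown network_input {self.network_input!r}")


def run_recovery(design: SyntheticDesign, min_abs_r: float = 0.90) -> dict:
    """Simulate a dataset, run the in-memory network pipeline and score it
    against the planted truth (no files written).

    Returns the :func:`estronet.synthetic_data.score_recovery` dict plus
    the intermediate objects under the ``objects`` key.
    """
    from .synthetic_data import score_recovery

    expr, deg, truth = simulate_dataset(design)
    kept, _ = gcn_gene_filter(deg)
    profiles = log2fc_profiles(expr)
    kept_profiles = ProfileMatrix(
        profiles.data.loc[kept], profiles.tissues, profiles.days
    )
    r = pearson_profiles(kept_profiles)
    mask, _ = pcit_mask(r)
    assignment = topology.assign_tissue(kept_profiles)
    net = build_network(r, mask, min_abs_r=min_abs_r, node_attrs=assignment.table)
    part = topology.partition_network(net, assignment)
    scores = score_recovery(truth, kept, assignment, part, net)
    scores["objects"] = {
        "truth": truth,
        "kept": kept,
        "profiles": kept_profiles,
        "assignment": assignment,
        "network": net,
        "partition": part,
    }
    return scores


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run summary (also written to
    ``<out_dir>/run_summary.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    def stage(name: str, **info) -> None:
        log.info("stage %s: %s", name, info)
        summary["stages"][name] = info

    # ---- input -----------------------------------------------------------
    if config.simulate:
        design = dataclasses.replace(config.design, seed=config.seed)
        expr, deg, truth = simulate_dataset(design)
        write_expression(expr, out / "fpkm.tsv", out / "samples.tsv")
        write_deg_table(deg, out / "deg.tsv")
        write_truth(truth, out / "truth.tsv")
        stage(
            "simulate",
            n_genes=len(expr.genes),
            n_samples=len(expr.samples),
            n_bridging_planted=len(truth.bridging_genes),
        )
    else:
        expr = read_expression(config.expression_path, config.metadata_path)
        deg = read_deg_table(config.deg_path)
        stage("load", n_genes=len(expr.genes), n_samples=len(expr.samples))

    annotation = (
        read_annotation(config.annotation_path)
        if config.annotation_path
        else GeneAnnotation()
    )

    # ---- stringent filter ------------------------------------------------
    kept, report = gcn_gene_filter(deg, annotation, config.filter)
    if not kept:
        raise RuntimeError("filter stage: no genes pass the three-rule filter")
    report.as_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    stage(
        "filter",
        n_input=deg["gene"].nunique(),
        n_kept=len(kept),
        n_removed_r1=len(report.removed_r1_no_significance),
        n_removed_r2=len(report.removed_r2_annotation),
        n_removed_r3=len(report.removed_r3_low_fold_change),
    )

    # ---- profiles --------------------------------------------------------
    profiles = log2fc_profiles(expr)
    kept_profiles = ProfileMatrix(
        profiles.data.loc[kept], profiles.tissues, profiles.days
    )
    kept_profiles.write(out / "profiles.tsv")
    stage("profiles", n_genes=len(kept), n_conditions=kept_profiles.data.shape[1])

    # ---- correlations + PCIT --------------------------------------------
    corr_data = (
        zscore_rows(kept_profiles.data)
        if config.network_input == "zscore"
        else kept_profiles.data
    )
    r = pearson_profiles(corr_data, on_zero_variance="drop")
    mask, diag = pcit_mask(r)
    stage(
        "pcit",
        n_genes=diag.n_genes,
        n_edges_input=diag.n_edges_input,
        n_edges_significant=diag.n_edges_significant,
        tolerance_mean=diag.tolerance_mean,
    )

    # ---- network ---------------------------------------------------------
    assignment = topology.assign_tissue(kept_profiles)
    assignment.table.to_csv(out / "tissue_assignment.tsv", sep="\t")
    net = build_network(
        r,
        mask,
        min_abs_r=config.min_abs_r,
        node_attrs=assignment.table,
        threshold_mode=config.threshold_mode,
    )
    stage("network", **topology.network_summary(net))

    # ---- partition -------------------------------------------------------
    part = topology.partition_network(net, assignment)
    for tissue, sub in part.subnetworks.items():
        topology.export_graph(sub, "graphml", out / f"subnetwork_{tissue}.graphml")
    nx.set_node_attributes(
        net, {n: (n in part.bridging) for n in net.nodes}, "bridging"
    )
    topology.export_graph(
        net,
        "graphml",
        out / "network.graphml",
        node_attr_path=out / "network_nodes.tsv",
        edge_attr_path=out / "network_edges.tsv",
    )
    if part.core is not None:
        topology.export_graph(part.core, "graphml", out / "core_network.graphml")
    stage(
        "partition",
        subnetworks={
            t: topology.network_summary(g) for t, g in part.subnetworks.items()
        },
        n_bridging=len(part.bridging),
        bridge_connectivity=part.bridge_connectivity,
        core=topology.network_summary(part.core),
        n_excluded={t: len(v) for t, v in part.excluded.items()},
        n_unassigned=len(part.unassigned),
    )

    # ---- expression-profile clustering ----------------------------------
    if config.choose_k_range is not None:
        lo, hi = config.choose_k_range
        best_k, score_table = choose_k(
            kept_profiles.data, range(lo, hi + 1), seed=config.seed
        )
        score_table.to_csv(out / "choose_k.tsv", sep="\t", index=False)
    else:
        best_k = config.cluster_k
    clusters = kmeans_profiles(
        kept_profiles.data,
        k=best_k,
        max_iter=config.cluster_max_iter,
        seed=config.seed,
    )
    clusters.assignment.rename_axis("gene").to_frame().to_csv(
        out / "clusters.tsv", sep="\t"
    )
    stage("cluster", k=best_k, inertia=clusters.inertia, n_iter=clusters.n_iter)

    # ---- optional enrichment --------------------------------------------
    if config.gmt_path:
        collection = read_gmt(config.gmt_path, universe=deg["gene"].unique())
        enrich = hypergeom_enrich(sorted(part.bridging) or kept, collection)
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        stage("enrich", n_sets=len(enrich), n_passing=int(enrich["passing"].sum()))

    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
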