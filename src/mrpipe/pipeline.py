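"""End-to-end orchestration of the per-sample MR workflow.

``run_all`` drives the stages quartile filter -> per-sample differential
expression -> TF activity -> causal MR calling -> merged MR states ->
feedback selection -> merged scores and biclustering -> network analysis
-> annotation, writing every stage's TSV outputs and a JSON manifest
(parameters, input checksums, seed, package version) into a run directory.
One global seed streams deterministic per-stage sub-seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, causal, diffexpr, feedback, network_analysis
from ._seeds import subseed
from .data_io import (
    CountMatrix,
    GeneSetCollection,
    RegulonSet,
    SignedNetwork,
    StateMatrix,
    read_count_matrix,
    read_gene_sets,
    read_regulons,
    read_signed_network,
    write_results_table,
    write_state_matrix,
)
from .diffexpr import DEConfig
from .regulon_activity import infer_tf_activity

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    counts_path: str = ""
    roles_path: str = ""
    network_path: str = ""
    regulons_path: str = ""
    gene_sets_path: str = ""
    immune_signature: str = ""  # gene set name inside gene_sets to score
    subtypes_path: str = ""
    out_dir: str = "mrpipe_run"

    lfc_threshold: float = 1.0
    alpha: float = 0.05
    pseudocount: float = 0.5
    dispersion_shrink: float = 0.8
    min_targets: int = 5
    delta_max: int = 3
    n_perm: int = 1000
    cos_threshold: float = 0.3
    n_boot: int = 1000
    n_draws: int = 1000
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    run_dir: Path
    deg_matrix: pd.DataFrame
    tf_states: StateMatrix
    mr_states: StateMatrix
    merged_states: StateMatrix
    feedback_records: list
    selected_mrs: list[str]
    merged_score_matrix: pd.DataFrame
    subnetwork_stats: network_analysis.SubnetworkStats | None = None
    controllability: network_analysis.ControllabilityResult | None = None
    extras: dict = field(default_factory=dict)


def _checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def merge_states(tf_states: StateMatrix, mr_states: StateMatrix) -> StateMatrix:
    """Merge TF-activity and causal MR calls into one state matrix.

    TF nodes keep their regulon-enrichment state; upstream nodes carry
    their causal call. A node present in both keeps the TF-activity state.
    """
    samples = [s for s in tf_states.sample_ids if s in mr_states.sample_ids]
    upstream = mr_states.values.reindex(columns=samples).drop(
        index=[n for n in mr_states.values.index if n in tf_states.values.index],
        errors="ignore",
    )
    merged = pd.concat([tf_states.values[samples], upstream]).sort_index()
    return StateMatrix(values=merged.astype(np.int64), tag="merged")


def run_all(
    config: PipelineConfig,
    counts: CountMatrix | None = None,
    network: SignedNetwork | None = None,
    regulons: RegulonSet | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> PipelineResult:
    """Run the whole workflow; inputs may be passed in memory or by path."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {},
        "stages": [],
    }
    for key in ("counts_path", "roles_path", "network_path", "regulons_path", "gene_sets_path"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": path, "sha256": _checksum(path)}

    if counts is None:
        counts = read_count_matrix(config.counts_path, roles_path=config.roles_path)
    if network is None:
        network = read_signed_network(config.network_path)
    if regulons is None:
        regulons = read_regulons(config.regulons_path)
    if gene_sets is None and config.gene_sets_path:
        gene_sets = read_gene_sets(config.gene_sets_path)

    de_config = DEConfig(
        lfc_threshold=config.lfc_threshold,
        alpha=config.alpha,
        pseudocount=config.pseudocount,
        dispersion_shrink=config.dispersion_shrink,
    )

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    stage("filter_low_expression")
    filtered = diffexpr.filter_low_expression(counts)

    stage("differential_expression")
    size_factors = diffexpr.estimate_size_factors(filtered)
    signatures, deg_matrix = diffexpr.call_all_degs(filtered, de_config)
    deg_out = deg_matrix.copy()
    deg_out.index.name = "gene_id"
    deg_out.to_csv(run_dir / "deg_matrix.tsv", sep="\t")
    sig_dir = run_dir / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for sample, sig in signatures.items():
        out = sig.copy()
        out.index.name = "gene_id"
        out.to_csv(sig_dir / f"{sample}.tsv", sep="\t")

    stage("tf_activity")
    tf_states, tf_calls = infer_tf_activity(
        signatures, regulons, alpha=config.alpha, min_targets=config.min_targets
    )
    write_state_matrix(tf_states, run_dir / "tf_states.tsv")
    write_results_table(tf_calls, run_dir / "tf_activity_calls.tsv")

    stage("causal_mr")
    mr_states, hypothesis_tables = causal.call_mrs(
        network,
        tf_states,
        delta_max=config.delta_max,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=subseed(config.seed, "causal"),
    )
    write_state_matrix(mr_states, run_dir / "mr_states.tsv")
    hyp_dir = run_dir / "hypotheses"
    hyp_dir.mkdir(exist_ok=True)
    for sample, table in hypothesis_tables.items():
        write_results_table(table, hyp_dir / f"{sample}.tsv")

    stage("merge_states")
    merged_states = merge_states(tf_states, mr_states)
    write_state_matrix(merged_states, run_dir / "merged_states.tsv")

    stage("feedback_selection")
    records = feedback.select_feedback_mrs(
        merged_states,
        deg_matrix,
        cos_threshold=config.cos_threshold,
        n_boot=config.n_boot,
        seed=subseed(config.seed, "feedback"),
    )
    fb_table = feedback.feedback_table(records)
    write_results_table(fb_table, run_dir / "feedback_records.tsv")
    selected = [r.protein for r in records if r.selected]

    stage("merged_scores_biclustering")
    score_matrix = feedback.merged_scores(merged_states, deg_matrix)
    score_out = score_matrix.copy()
    score_out.index.name = "protein_id"
    score_out.to_csv(run_dir / "merged_scores.tsv", sep="\t")
    extras: dict = {}
    nonzero = score_matrix.loc[(score_matrix != 0).any(axis=1)]
    if nonzero.shape[0] >= 2 and nonzero.shape[1] >= 2:
        clustering = feedback.bicluster(nonzero)
        extras["clustering"] = clustering
        (run_dir / "row_dendrogram.nwk").write_text(
            feedback.linkage_to_newick(clustering.row_linkage, list(nonzero.index))
        )
        (run_dir / "col_dendrogram.nwk").write_text(
            feedback.linkage_to_newick(clustering.col_linkage, list(nonzero.columns))
        )
        order = pd.DataFrame(
            {
                "axis": ["row"] * len(clustering.row_order) + ["col"] * len(clustering.col_order),
                "position": list(range(len(clustering.row_order))) + list(range(len(clustering.col_order))),
                "label": [nonzero.index[i] for i in clustering.row_order]
                + [nonzero.columns[i] for i in clustering.col_order],
            }
        )
        write_results_table(order, run_dir / "cluster_orders.tsv")
    else:
        logger.warning("merged score matrix too small/empty for biclustering; skipped")

    stage("network_analysis")
    subnetwork_stats = None
    controllability = None
    if selected:
        sub, subnetwork_stats = network_analysis.induce_mr_subnetwork(network, selected)
        if subnetwork_stats.n_nodes_in_network:
            subnetwork_stats.null_summary = network_analysis.random_subnetwork_null(
                network,
                subnetwork_stats.n_nodes_in_network,
                n_draws=config.n_draws,
                seed=subseed(config.seed, "null"),
            )
        if sub.n_nodes:
            controllability = network_analysis.mds_drivers(sub)
            cent = network_analysis.centrality_table(network_analysis.centralities(sub))
            write_results_table(cent, run_dir / "centralities.tsv")
            write_results_table(
                pd.DataFrame(
                    {
                        "n_drivers": [controllability.n_drivers],
                        "matching_size": [controllability.matching_size],
                        "witness_driver_set": [",".join(controllability.witness_driver_set)],
                    }
                ),
                run_dir / "controllability.tsv",
            )
        stats_row = {
            "n_nodes_in_network": subnetwork_stats.n_nodes_in_network,
            "n_connected_in_lcc": subnetwork_stats.n_connected_in_lcc,
            "n_edges_in_lcc": subnetwork_stats.n_edges_in_lcc,
            **{f"null_{k}": v for k, v in subnetwork_stats.null_summary.items()},
        }
        write_results_table(pd.DataFrame([stats_row]), run_dir / "subnetwork_stats.tsv")

    stage("tf_target_network")
    tf_edges, tf_outdeg = network_analysis.build_tf_target_network(
        tf_states,
        deg_matrix,
        regulons,
        cos_threshold=config.cos_threshold,
        n_boot=config.n_boot,
        seed=subseed(config.seed, "tf_target"),
        mr_genes=selected,
    )
    write_results_table(tf_edges, run_dir / "tf_target_edges.tsv")
    write_results_table(tf_outdeg, run_dir / "tf_target_outdegrees.tsv")

    stage("annotation")
    if gene_sets is not None and selected:
        enrichment = annotation.ora_enrich(selected, list(filtered.gene_ids), gene_sets)
        write_results_table(enrichment, run_dir / "enrichment.tsv")
        extras["enrichment"] = enrichment
        if config.immune_signature and config.immune_signature in dict(gene_sets.items()):
            normalized = filtered.counts / size_factors
            scores = annotation.immune_score(
                normalized[filtered.tumor_ids],
                gene_sets.members(config.immune_signature),
            )
            corr = annotation.kendall_screen_all(
                merged_states.values, normalized, scores, alpha=config.alpha
            )
            write_results_table(corr, run_dir / "immune_correlations.tsv")
            extras["immune_scores"] = scores

    with open(run_dir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)

    return PipelineResult(
        run_dir=run_dir,
        deg_matrix=deg_matrix,
        tf_states=tf_states,
        mr_states=mr_states,
        merged_states=merged_states,
        feedback_records=records,
        selected_mrs=selected,
        merged_score_matrix=score_matrix,
        subnetwork_stats=subnetwork_stats,
        controllability=controllability,
        extras=extras,
    )
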