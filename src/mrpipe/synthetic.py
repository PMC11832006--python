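"""Synthetic study generator with planted ground truth.

Emulates the statistical structure the pipeline assumes: a three-layer
signed signaling network (upstream regulators -> signaling intermediates ->
TFs), signed regulons over a gene universe, per-tumor-sample planted
regulator activities, and negative-binomial RNA-seq counts whose expression
shifts are driven through the network. Each planted regulator also shifts
its own encoding gene in the direction of its state, planting the positive
feedback loops the downstream selection stage looks for.

Truth propagation deliberately uses the same signed shortest-path semantics
as :mod:`mrpipe.causal` (conflicting sign products -> no effect) so that
recovery of the planted truth is well-posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._seeds import subseed
from .causal import AMBIGUOUS, signed_shortest_paths
from .data_io import (
    TUMOR,
    REFERENCE,
    CountMatrix,
    RegulonSet,
    SignedNetwork,
    SingleCellMatrix,
    StateMatrix,
)

logger = logging.getLogger(__name__)

MR_LAYER = "MR"
SIGNAL_LAYER = "SIG"
TF_LAYER = "TF"


class ConfigError(ValueError):
    """Impossible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic bulk experiment.

    Defaults mirror the real study's design at reduced scale: a handful of
    reference samples against a few dozen tumor samples, ~4:1 active to
    inactive planted regulators, a two-unit log2 effect size and mild
    negative-binomial overdispersion.
    """

    n_mr_layer: int = 10
    n_tf: int = 20
    n_genes: int = 1000
    n_tumor: int = 30
    n_reference: int = 5
    regulon_size_range: tuple[int, int] = (8, 15)
    edge_density: float = 0.35
    inhibitory_fraction: float = 0.35
    planted_lfc: float = 2.0
    nb_dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (20.0, 2000.0)
    active_fraction: float = 0.30
    inactive_fraction: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mr_layer", "n_tf", "n_genes", "n_tumor", "n_reference"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("edge_density", "inhibitory_fraction", "active_fraction", "inactive_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.active_fraction + self.inactive_fraction > 1.0:
            raise ConfigError("active_fraction + inactive_fraction must be <= 1")
        if self.planted_lfc < 0:
            raise ConfigError("planted_lfc must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        lo, hi = self.regulon_size_range
        if not (1 <= lo <= hi):
            raise ConfigError("regulon_size_range must be a positive interval")
        if not (0 < self.base_mean_range[0] <= self.base_mean_range[1]):
            raise ConfigError("base_mean_range must be a positive interval")

    @property
    def node_ids(self) -> dict[str, list[str]]:
        return {
            MR_LAYER: [f"MR{i:02d}" for i in range(1, self.n_mr_layer + 1)],
            SIGNAL_LAYER: [f"SIG{i:02d}" for i in range(1, self.n_mr_layer + 1)],
            TF_LAYER: [f"TF{i:02d}" for i in range(1, self.n_tf + 1)],
        }

    @property
    def tumor_ids(self) -> list[str]:
        return [f"T{i:03d}" for i in range(1, self.n_tumor + 1)]

    @property
    def reference_ids(self) -> list[str]:
        return [f"R{i:03d}" for i in range(1, self.n_reference + 1)]


@dataclass
class TruthTable:
    """Planted ground truth for one simulated study.

    ``states`` holds the planted/propagated state of every network node in
    every tumor sample; ``gene_lfc`` the planted signed log2 fold change of
    every gene; ``mr_layer`` names the top-layer regulators eligible for
    the planted feedback rule; ``tf_targets`` maps each TF to the genes its
    activity shifts.
    """

    states: StateMatrix
    gene_lfc: pd.DataFrame
    mr_layer: list[str] = field(default_factory=list)
    tf_targets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def feedback_mrs(self) -> list[str]:
        """Top-layer regulators planted nonzero in at least one sample."""
        sub = self.states.values.loc[self.mr_layer]
        return list(sub.index[(sub != 0).any(axis=1)])


def generate_network_and_regulons(
    config: SimulationConfig,
) -> tuple[SignedNetwork, RegulonSet, dict[str, str]]:
    """Generate the layered signed network and TF regulons.

    Edges run MR layer -> signaling layer -> TF layer, each present with
    probability ``edge_density`` and inhibitory with probability
    ``inhibitory_fraction``; every non-terminal node is guaranteed at least
    one outgoing edge so no regulator is trivially disconnected. Regulon
    targets are drawn from the background gene universe (node-encoding
    genes excluded) so the only planted transcriptional feedback is the
    explicit feedback rule of :func:`plant_truth`.
    """
    rng = np.random.default_rng(subseed(config.seed, "network"))
    layers = config.node_ids
    layer_of = {n: layer for layer, nodes in layers.items() for n in nodes}
    n_nodes = len(layer_of)
    background = background_genes(config)
    lo, hi = config.regulon_size_range
    if hi > len(background):
        raise ConfigError(
            f"regulon_size_range upper bound {hi} exceeds the {len(background)} "
            f"background genes available in a universe of {config.n_genes}"
        )

    def wire(sources: list[str], targets: list[str], min_out: int) -> list[tuple[str, str, int]]:
        edges = []
        for src in sources:
            mask = rng.random(len(targets)) < config.edge_density
            chosen = [t for t, m in zip(targets, mask) if m]
            while len(chosen) < min(min_out, len(targets)):
                extra = targets[rng.integers(len(targets))]
                if extra not in chosen:
                    chosen.append(extra)
            for tgt in chosen:
                sign = -1 if rng.random() < config.inhibitory_fraction else 1
                edges.append((src, tgt, sign))
        return edges

    # top-layer regulators are pleiotropic by definition: guarantee fan-out >= 2
    edges = wire(layers[MR_LAYER], layers[SIGNAL_LAYER], min_out=2)
    edges += wire(layers[SIGNAL_LAYER], layers[TF_LAYER], min_out=1)
    network = SignedNetwork(edges=edges, nodes=set(layer_of))
    if network.n_nodes != n_nodes:
        raise AssertionError("layer bookkeeping out of sync")

    regulons: dict[str, dict[str, int]] = {}
    for tf in layers[TF_LAYER]:
        size = int(rng.integers(lo, hi + 1))
        targets = rng.choice(len(background), size=size, replace=False)
        modes = np.where(rng.random(size) < 0.5, -1, 1)
        regulons[tf] = {background[i]: int(m) for i, m in zip(sorted(targets), modes)}
    return network, RegulonSet(regulons=regulons), layer_of


def background_genes(config: SimulationConfig) -> list[str]:
    """Gene ids not encoding a network node."""
    n_nodes = 2 * config.n_mr_layer + config.n_tf
    n_background = config.n_genes - n_nodes
    if n_background < 1:
        raise ConfigError(
            f"n_genes={config.n_genes} leaves no background genes beyond the "
            f"{n_nodes} node-encoding genes"
        )
    return [f"G{i:04d}" for i in range(1, n_background + 1)]


def gene_universe(config: SimulationConfig) -> list[str]:
    """All gene ids: one per network node (same id) plus background genes."""
    layers = config.node_ids
    node_genes = layers[MR_LAYER] + layers[SIGNAL_LAYER] + layers[TF_LAYER]
    return node_genes + background_genes(config)


def plant_truth(
    network: SignedNetwork, regulons: RegulonSet, config: SimulationConfig
) -> TruthTable:
    """Plant per-sample regulator states and derive gene-level effects.

    Each top-layer regulator is planted +1 with probability
    ``active_fraction`` and -1 with ``inactive_fraction`` independently per
    tumor sample. States propagate downstream along signed shortest paths;
    nodes receiving conflicting influences stay at 0. A TF with state t
    shifts each regulon target by t*mode*planted_lfc (conflicting TF
    influences on a gene cancel to 0), and each planted regulator's own
    encoding gene is shifted by state*planted_lfc (feedback).
    """
    rng = np.random.default_rng(subseed(config.seed, "truth"))
    layers = config.node_ids
    mr_nodes = layers[MR_LAYER]
    all_nodes = sorted(network.nodes)
    genes = gene_universe(config)
    samples = config.tumor_ids

    # signed reach of every top-layer regulator, computed once
    depth = 3  # MR -> SIG -> TF needs 2; 3 leaves headroom for custom graphs
    reaches = {mr: signed_shortest_paths(network, mr, depth) for mr in mr_nodes}

    states = pd.DataFrame(0, index=all_nodes, columns=samples, dtype=np.int64)
    gene_lfc = pd.DataFrame(0.0, index=genes, columns=samples)
    tf_targets = {tf: sorted(regulons[tf]) for tf in regulons.tf_ids}

    for sample in samples:
        draws = rng.random(len(mr_nodes))
        planted = np.where(
            draws < config.active_fraction,
            1,
            np.where(draws < config.active_fraction + config.inactive_fraction, -1, 0),
        )
        planted_map = {mr: int(s) for mr, s in zip(mr_nodes, planted) if s != 0}
        # combine influences additively: state = sign of the summed signed
        # influences (ambiguous paths contribute nothing; exact ties -> 0)
        influence: dict[str, int] = {}
        for mr, s in planted_map.items():
            reach = reaches[mr]
            for node, sigma in reach.signs.items():
                if sigma == AMBIGUOUS:
                    continue
                influence[node] = influence.get(node, 0) + s * sigma
        for node, total in influence.items():
            states.loc[node, sample] = int(np.sign(total))
        # gene shifts from TF states, combined the same way
        direction: dict[str, int] = {}
        for tf in regulons.tf_ids:
            t = int(states.loc[tf, sample]) if tf in states.index else 0
            if t == 0:
                continue
            for gene, mode in regulons[tf].items():
                direction[gene] = direction.get(gene, 0) + t * mode
        for gene, total in direction.items():
            gene_lfc.loc[gene, sample] = int(np.sign(total)) * config.planted_lfc
        # feedback: the planted regulator's own gene moves with its state
        for mr, s in planted_map.items():
            gene_lfc.loc[mr, sample] = s * config.planted_lfc

    return TruthTable(
        states=StateMatrix(values=states, tag="merged"),
        gene_lfc=gene_lfc,
        mr_layer=list(mr_nodes),
        tf_targets=tf_targets,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, phi) with variance mean*(1 + phi*mean); Poisson at phi=0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    truth: TruthTable, regulons: RegulonSet, config: SimulationConfig
) -> CountMatrix:
    """Draw negative-binomial counts around the planted fold changes.

    Baseline means are log-uniform over ``base_mean_range``; node-encoding
    genes draw from the upper three quartiles of that range, mirroring the
    restriction of the signaling network to expressed genes. Reference
    samples draw NB(mu, phi); tumor sample s draws NB(mu * 2**delta, phi)
    with delta the planted signed log2 fold change.
    """
    rng = np.random.default_rng(subseed(config.seed, "counts"))
    genes = list(truth.gene_lfc.index)
    node_genes = set(gene_universe(config)) - set(background_genes(config))
    lo, hi = np.log(config.base_mean_range[0]), np.log(config.base_mean_range[1])
    u = rng.random(len(genes))
    is_node = np.array([g in node_genes for g in genes])
    # node genes: upper 75% of the log range (quartile-filter survivors)
    u[is_node] = 0.25 + 0.75 * u[is_node]
    base_mean = np.exp(lo + (hi - lo) * u)

    columns = {}
    for sample in config.reference_ids:
        columns[sample] = _nb_draw(rng, base_mean, config.nb_dispersion)
    for sample in config.tumor_ids:
        delta = truth.gene_lfc[sample].to_numpy()
        columns[sample] = _nb_draw(rng, base_mean * 2.0**delta, config.nb_dispersion)

    counts = pd.DataFrame(columns, index=genes)
    roles = pd.Series(
        {s: REFERENCE for s in config.reference_ids} | {s: TUMOR for s in config.tumor_ids}
    )
    return CountMatrix(counts=counts, roles=roles)


def simulate_study(
    config: SimulationConfig,
) -> tuple[CountMatrix, SignedNetwork, RegulonSet, TruthTable]:
    """Generate a complete synthetic study (network, regulons, truth, counts)."""
    network, regulons, _ = generate_network_and_regulons(config)
    truth = plant_truth(network, regulons, config)
    counts = simulate_counts(truth, regulons, config)
    return counts, network, regulons, truth


# ---------------------------------------------------------------------------
# single-cell fixture generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SingleCellConfig:
    """Bernoulli-expression tpm simulator for cell-type summary tests.

    ``expression_prob[gene][cell_type]`` is the probability a cell of that
    type expresses the gene; expressed cells draw tpm ~ Exp(mean_tpm).
    """

    cells_per_type: Mapping[str, int]
    expression_prob: Mapping[str, Mapping[str, float]]
    mean_tpm: float = 50.0
    seed: int = 0


def simulate_single_cell(config: SingleCellConfig) -> SingleCellMatrix:
    rng = np.random.default_rng(subseed(config.seed, "single_cell"))
    cell_ids = []
    labels = []
    for cell_type, n in config.cells_per_type.items():
        if n < 1:
            raise ConfigError(f"cell type {cell_type!r} has no cells")
        for i in range(1, n + 1):
            cell_ids.append(f"{cell_type}_{i:04d}")
            labels.append(cell_type)
    genes = list(config.expression_prob)
    tpm = np.zeros((len(genes), len(cell_ids)))
    for gi, gene in enumerate(genes):
        probs = config.expression_prob[gene]
        for ci, (cell, label) in enumerate(zip(cell_ids, labels)):
            p = probs.get(label, 0.0)
            if p > 0 and rng.random() < p:
                tpm[gi, ci] = rng.exponential(config.mean_tpm)
    return SingleCellMatrix(
        tpm=pd.DataFrame(tpm, index=genes, columns=cell_ids),
        cell_types=pd.Series(labels, index=cell_ids),
    )


def scaled(config: SimulationConfig, **overrides) -> SimulationConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
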