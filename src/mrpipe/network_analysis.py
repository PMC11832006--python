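"""MR subnetwork statistics, structural controllability and centralities.

The selected regulators are projected onto the signaling network; the
induced subgraph's largest weakly connected component is compared against
uniformly drawn random node subsets of the same size. Structural
controllability follows the maximum-matching characterization: the minimum
number of driver nodes of a directed network equals max(1, N - size of a
maximum matching) in the bipartite out-copy/in-copy graph, and the
unmatched in-copies are a valid driver set. Directed out-degree and
outgoing closeness centralities rank regulators by downstream influence.

The bulk TF-target network retains a regulon interaction when the TF's
state vector and the target's DEG vector agree with the annotated mode by
the same cosine/bootstrap criterion used for feedback selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._seeds import subseed
from .data_io import RegulonSet, SignedNetwork, StateMatrix
from .feedback import bootstrap_ci, cosine

logger = logging.getLogger(__name__)


@dataclass
class SubnetworkStats:
    n_nodes_in_network: int
    n_connected_in_lcc: int
    n_edges_in_lcc: int
    null_summary: dict = field(default_factory=dict)


@dataclass
class ControllabilityResult:
    n_drivers: int
    witness_driver_set: list[str]
    matching_size: int


@dataclass
class CentralityRecord:
    node: str
    outdegree: int
    closeness: float


def _weak_components(network: SignedNetwork) -> list[set]:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((u, v) for u, v, _ in network.edges)
    return [set(c) for c in nx.connected_components(g)]


def _lcc(network: SignedNetwork) -> tuple[set, int]:
    """Largest weakly connected component and its internal edge count."""
    if not network.nodes:
        return set(), 0
    components = _weak_components(network)
    lcc = max(components, key=lambda c: (len(c), sorted(c)))
    n_edges = sum(1 for u, v, _ in network.edges if u in lcc and v in lcc)
    return lcc, n_edges


def induce_mr_subnetwork(
    network: SignedNetwork, mr_ids: list[str]
) -> tuple[SignedNetwork, SubnetworkStats]:
    """Induced subgraph on the regulators present in the network."""
    present = set(mr_ids) & network.nodes
    sub = network.subgraph(present)
    lcc, n_edges = _lcc(sub)
    stats = SubnetworkStats(
        n_nodes_in_network=len(present),
        n_connected_in_lcc=len(lcc),
        n_edges_in_lcc=n_edges,
    )
    return sub, stats


def random_subnetwork_null(
    network: SignedNetwork, k: int, n_draws: int = 1000, seed: int = 0
) -> dict:
    """LCC size / edge count null over uniform node subsets of size k."""
    nodes = sorted(network.nodes)
    if k > len(nodes):
        raise ValueError(f"k={k} exceeds the {len(nodes)} network nodes")
    rng = np.random.default_rng(subseed(seed, "subnetwork_null"))
    lcc_sizes = np.empty(n_draws, dtype=np.int64)
    edge_counts = np.empty(n_draws, dtype=np.int64)
    for i in range(n_draws):
        chosen = rng.choice(len(nodes), size=k, replace=False)
        keep = {nodes[j] for j in chosen}
        sub = network.subgraph(keep)
        lcc, n_edges = _lcc(sub)
        lcc_sizes[i] = len(lcc)
        edge_counts[i] = n_edges
    return {
        "lcc_size_median": float(np.median(lcc_sizes)),
        "lcc_size_max": int(lcc_sizes.max()),
        "edge_count_median": float(np.median(edge_counts)),
        "edge_count_max": int(edge_counts.max()),
        "n_draws": n_draws,
        "k": k,
    }


def mds_drivers(network: SignedNetwork) -> ControllabilityResult:
    """Minimum driver node set via maximum bipartite matching.

    Each node contributes an out-copy and an in-copy; every distinct arc
    (u, v) becomes a bipartite edge between u's out-copy and v's in-copy.
    Nodes whose in-copy is unmatched in a maximum matching form a minimum
    driver set; n_drivers = max(1, N - matching size).
    """
    if not network.nodes:
        raise ValueError("empty network")
    arcs = sorted({(u, v) for u, v, _ in network.edges})
    nodes = sorted(network.nodes)
    g = nx.Graph()
    out_copies = [("out", u) for u in nodes]
    g.add_nodes_from(out_copies, bipartite=0)
    g.add_nodes_from((("in", v) for v in nodes), bipartite=1)
    g.add_edges_from((("out", u), ("in", v)) for u, v in arcs)
    matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=out_copies)
    matching_size = sum(1 for k in matching if k[0] == "out")
    unmatched = sorted(v for v in nodes if ("in", v) not in matching)
    n_drivers = max(1, len(nodes) - matching_size)
    witness = unmatched if unmatched else [nodes[0]]
    return ControllabilityResult(
        n_drivers=n_drivers,
        witness_driver_set=witness,
        matching_size=matching_size,
    )


def centralities(network: SignedNetwork) -> list[CentralityRecord]:
    """Directed out-degree (distinct out-neighbors) and outgoing closeness.

    Closeness of u is 1 / sum of shortest-path lengths from u to every
    node reachable from it (0 when nothing is reachable).
    """
    g = network.to_networkx()
    records = []
    for node in sorted(network.nodes):
        outdeg = g.out_degree(node)
        lengths = nx.single_source_shortest_path_length(g, node)
        total = sum(d for n, d in lengths.items() if n != node)
        closeness = 1.0 / total if total > 0 else 0.0
        records.append(CentralityRecord(node=node, outdegree=outdeg, closeness=closeness))
    return records


def centrality_table(records: list[CentralityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": [r.node for r in records],
            "outdegree": [r.outdegree for r in records],
            "closeness": [r.closeness for r in records],
        }
    )


def build_tf_target_network(
    tf_states: StateMatrix,
    deg_calls: pd.DataFrame,
    regulons: RegulonSet,
    cos_threshold: float = 0.3,
    n_boot: int = 1000,
    seed: int = 0,
    mr_genes: list[str] | None = None,
    literal_ci: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk TF-target network from regulons, TF states and DEG calls.

    An annotated stimulation (mode +1) is kept when cosine(TF state vector,
    target DEG vector) > cos_threshold with CI lower bound > 0; an
    annotated repression (mode -1) when cosine < -cos_threshold with CI
    upper bound < 0 (or, with ``literal_ci=True``, CI lower bound < 0).
    Returns the evaluated edge table and per-TF out-degrees over all
    included targets and over targets restricted to ``mr_genes``.
    """
    samples = [s for s in tf_states.sample_ids if s in deg_calls.columns]
    if not samples:
        raise ValueError("TF state matrix and DEG matrix share no samples")
    mr_genes_set = set(mr_genes) if mr_genes is not None else set()
    rows = []
    for tf in regulons.tf_ids:
        if tf not in tf_states.values.index:
            continue
        state_vec = tf_states.values.loc[tf, samples].to_numpy()
        for target, mode in regulons[tf].items():
            if target not in deg_calls.index:
                continue
            deg_vec = deg_calls.loc[target, samples].to_numpy()
            cos = cosine(state_vec, deg_vec)
            ci_low, ci_high = bootstrap_ci(
                state_vec, deg_vec, n_boot=n_boot,
                seed=subseed(seed, "tf_target", tf, target),
            )
            if mode == 1:
                included = cos > cos_threshold and ci_low > 0
            elif literal_ci:
                included = cos < -cos_threshold and ci_low < 0
            else:
                included = cos < -cos_threshold and ci_high < 0
            rows.append((tf, target, mode, cos, ci_low, ci_high, included))
    edges = pd.DataFrame(
        rows,
        columns=["tf", "target", "mode", "cosine", "ci_low", "ci_high", "included"],
    )
    kept = edges[edges["included"]]
    tf_ids = sorted(edges["tf"].unique())
    outdeg_all = kept.groupby("tf").size().reindex(tf_ids).fillna(0).astype(int)
    kept_mr = kept[kept["target"].isin(mr_genes_set)]
    outdeg_mr = kept_mr.groupby("tf").size().reindex(tf_ids).fillna(0).astype(int)
    outdegrees = pd.DataFrame(
        {"tf": tf_ids, "outdegree_all": outdeg_all.to_numpy(), "outdegree_mr": outdeg_mr.to_numpy()}
    )
    return edges, outdegrees
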