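"""Domain types and readers/writers for the formats the pipeline touches.

All tabular formats are UTF-8 TSV with a header row; gene sets use the
standard GMT layout; networks may also be given as three-column SIF.
Identifiers are opaque case-sensitive strings (HGNC symbols in practice);
no identifier mapping is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
REFERENCE = "reference"

#: accepted edge/regulon sign tokens (OmniPath / CollecTRI export dialects)
SIGN_TOKENS = {
    "+1": 1,
    "1": 1,
    "-1": -1,
    "−1": -1,  # unicode minus
    "activates": 1,
    "activation": 1,
    "stimulation": 1,
    "inhibits": -1,
    "inhibition": -1,
    "repression": -1,
}


class FormatError(ValueError):
    """A file violates its documented dialect."""


def _parse_sign(token: str, context: str) -> int:
    try:
        return SIGN_TOKENS[str(token).strip()]
    except KeyError:
        raise FormatError(f"unknown sign token {token!r} in {context}") from None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample matrix with sample roles.

    ``roles`` maps every sample id to ``"tumor"`` or ``"reference"``.
    ``library_sizes`` are the per-sample column sums.
    """

    counts: pd.DataFrame
    roles: pd.Series

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts")
        if np.isnan(values.astype(float)).any():
            raise FormatError("missing values are not allowed in count matrices")
        if (values < 0).any():
            raise FormatError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise FormatError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self.roles = pd.Series(self.roles).reindex(self.counts.columns)
        if self.roles.isna().any():
            missing = self.roles.index[self.roles.isna()][0]
            raise FormatError(f"no role for sample {missing!r}")
        bad = set(self.roles.unique()) - {TUMOR, REFERENCE}
        if bad:
            raise FormatError(f"unknown sample role(s) {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == TUMOR])

    @property
    def reference_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == REFERENCE])

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.roles.copy())


@dataclass
class SignedNetwork:
    """Directed signed graph; edges are (source, target, sign) triples.

    A node pair may carry both an activating and an inhibiting edge
    (distinct triples); duplicated identical triples are collapsed.
    """

    edges: list[tuple[str, str, int]]
    nodes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        clean: list[tuple[str, str, int]] = []
        for source, target, sign in self.edges:
            if sign not in (1, -1):
                raise FormatError(
                    f"edge ({source!r}, {target!r}) has sign {sign!r}, expected +1/-1"
                )
            triple = (str(source), str(target), int(sign))
            if triple in seen:
                logger.warning("duplicate edge %s collapsed", triple)
                continue
            seen.add(triple)
            clean.append(triple)
        self.edges = clean
        self.nodes = set(self.nodes)
        for source, target, _ in self.edges:
            self.nodes.add(source)
            self.nodes.add(target)
        self._adj: dict[str, list[tuple[str, int]]] = {}
        for source, target, sign in self.edges:
            self._adj.setdefault(source, []).append((target, sign))

    def successors(self, node: str) -> list[tuple[str, int]]:
        return self._adj.get(node, [])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def subgraph(self, keep: Iterable[str]) -> "SignedNetwork":
        keep = set(keep)
        edges = [e for e in self.edges if e[0] in keep and e[1] in keep]
        return SignedNetwork(edges=edges, nodes=keep & self.nodes)

    def to_networkx(self):
        """Collapsed simple DiGraph (parallel opposite-sign arcs merged)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for source, target, sign in sorted(self.edges):
            if g.has_edge(source, target):
                if g[source][target]["sign"] != sign:
                    g[source][target]["sign"] = 0  # both signs present
            else:
                g.add_edge(source, target, sign=sign)
        return g


@dataclass
class RegulonSet:
    """Map TF id -> {target gene: mode} with mode +1 (stimulation) / -1 (repression)."""

    regulons: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            if not targets:
                raise FormatError(f"empty regulon for TF {tf!r}")
            for gene, mode in targets.items():
                if mode not in (1, -1):
                    raise FormatError(
                        f"regulon {tf!r} target {gene!r} has mode {mode!r}"
                    )

    @property
    def tf_ids(self) -> list[str]:
        return list(self.regulons)

    def __getitem__(self, tf: str) -> dict[str, int]:
        return self.regulons[tf]

    def __len__(self) -> int:
        return len(self.regulons)

    def items(self):
        return self.regulons.items()


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT contents)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"empty gene set {name!r}")

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class StateMatrix:
    """Discrete protein x sample matrix over {-1, 0, +1}.

    -1 = inactive, 0 = not identified, +1 = active. ``tag`` records which
    stage produced it (``"TF"``, ``"MR"`` or ``"merged"``).
    """

    values: pd.DataFrame
    tag: str = "MR"

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        arr = self.values.to_numpy()
        if not np.isin(arr, (-1, 0, 1)).all():
            raise FormatError("state matrix entries must be in {-1, 0, +1}")
        self.values = self.values.astype(np.int64)
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise FormatError("duplicate ids in state matrix")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SingleCellMatrix:
    """Gene x cell tpm matrix with a cell-type label per cell."""

    tpm: pd.DataFrame
    cell_types: pd.Series

    def __post_init__(self) -> None:
        self.tpm = pd.DataFrame(self.tpm)
        arr = self.tpm.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise FormatError("tpm values must be finite and >= 0")
        self.cell_types = pd.Series(self.cell_types).reindex(self.tpm.columns)
        if self.cell_types.isna().any():
            missing = self.cell_types.index[self.cell_types.isna()][0]
            raise FormatError(f"cell {missing!r} has no type label")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_count_matrix(
    path: str | Path,
    roles: Mapping[str, str] | None = None,
    roles_path: str | Path | None = None,
) -> CountMatrix:
    """Read a gene x sample count TSV (first column gene ids, header samples).

    Roles come either from ``roles`` (sample -> tumor/reference) or from a
    two-column sidecar TSV ``roles_path`` with columns sample_id, role.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = None
    if roles is None:
        if roles_path is None:
            raise ValueError("sample roles required: pass roles= or roles_path=")
        sidecar = pd.read_csv(roles_path, sep="\t")
        if sidecar.shape[1] < 2:
            raise FormatError(f"roles file {roles_path} needs two columns")
        roles = dict(zip(sidecar.iloc[:, 0].astype(str), sidecar.iloc[:, 1]))
    try:
        return CountMatrix(table, pd.Series(dict(roles)))
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from None


def write_count_matrix(cm: CountMatrix, path: str | Path, roles_path: str | Path | None = None) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if roles_path is not None:
        pd.DataFrame({"sample_id": cm.roles.index, "role": cm.roles.to_numpy()}).to_csv(
            roles_path, sep="\t", index=False
        )


def read_signed_network(path: str | Path) -> SignedNetwork:
    """Read a signed edge list: columns source, sign, target (TSV or SIF).

    A first line ``source<TAB>sign<TAB>target`` is treated as a header.
    """
    edges: list[tuple[str, str, int]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            source, sign_token, target = (f.strip() for f in fields)
            if lineno == 1 and sign_token.lower() in ("sign", "interaction"):
                continue
            sign = _parse_sign(sign_token, f"{path}:{lineno}")
            edges.append((source, target, sign))
    return SignedNetwork(edges=edges)


def write_signed_network(network: SignedNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("source\tsign\ttarget\n")
        for source, target, sign in network.edges:
            handle.write(f"{source}\t{sign:+d}\t{target}\n")


def read_regulons(path: str | Path) -> RegulonSet:
    """Read a regulon TSV: columns tf, target, mode (CollecTRI-style export)."""
    regulons: dict[str, dict[str, int]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            tf, target, mode_token = fields
            if lineno == 1 and mode_token.lower() in ("mode", "sign", "mor"):
                continue
            mode = _parse_sign(mode_token, f"{path}:{lineno}")
            bucket = regulons.setdefault(tf, {})
            if target in bucket:
                raise FormatError(
                    f"{path}:{lineno}: duplicate target {target!r} in regulon {tf!r}"
                )
            bucket[target] = mode
    return RegulonSet(regulons=regulons)


def write_regulons(regulons: RegulonSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("tf\ttarget\tmode\n")
        for tf, targets in regulons.items():
            for target, mode in targets.items():
                handle.write(f"{tf}\t{target}\t{mode:+d}\n")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description = fields[0], fields[1]
            members = [f for f in fields[2:] if f]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = (description, members)
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, (description, members) in collection.items():
            handle.write("\t".join([name, description] + list(members)) + "\n")


def read_state_matrix(path: str | Path, tag: str = "MR") -> StateMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = None
    return StateMatrix(values=table, tag=tag)


def write_state_matrix(sm: StateMatrix, path: str | Path) -> None:
    out = sm.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def write_results_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as UTF-8 TSV with header."""
    table.to_csv(path, sep="\t", index=index)
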