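"""Positive-feedback-loop MR selection, merged scoring and biclustering.

A regulator that truly drives expression changes should regulate its own
encoding gene: across samples, its discrete state vector (+1 active, -1
inactive, 0 absent) should resemble the discrete differential-expression
vector of its gene. Similarity is measured by cosine; a regulator is kept
when the cosine exceeds a threshold and the bootstrap 95% confidence
interval stays above zero.

For display and subtype analysis the state and DEG vectors are merged into
a single integer score in -3..3 (3 = active and up-regulated, 2 = active
only, 1 = up-regulated only; negatives mirror for inactive/down; sign
conflicts score 0), and both regulators and samples are clustered with
Ward linkage on 1 - cosine distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

from ._seeds import subseed
from .data_io import StateMatrix

logger = logging.getLogger(__name__)


@dataclass
class FeedbackRecord:
    protein: str
    cosine: float
    ci_low: float
    ci_high: float
    selected: bool
    reason: str = ""


@dataclass
class ClusteringResult:
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    method: str = "ward on 1-cosine distances (Lance-Williams, ward.D2 convention)"


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity with the zero-norm convention cos(0, .) = 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))


def bootstrap_ci(
    u: np.ndarray,
    v: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the cosine of two paired vectors.

    Positions are resampled with replacement; the zero-norm convention
    applies within each replicate.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("need paired 1-d vectors of length >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(u), size=(n_boot, len(u)))
    us = u[idx]
    vs = v[idx]
    dots = (us * vs).sum(axis=1)
    norms = np.linalg.norm(us, axis=1) * np.linalg.norm(vs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = np.where(norms > 0, dots / np.where(norms > 0, norms, 1.0), 0.0)
    lo, hi = np.percentile(cosines, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def select_feedback_mrs(
    mr_states: StateMatrix,
    deg_calls: pd.DataFrame,
    cos_threshold: float = 0.3,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> list[FeedbackRecord]:
    """Select regulators whose state tracks their own gene's DEG calls.

    One record per regulator in ``mr_states``; regulators whose encoding
    gene is absent from ``deg_calls`` are retained as unselected (logged),
    never dropped. Selection requires cosine > cos_threshold and a
    bootstrap CI lower bound > 0.
    """
    samples = [s for s in mr_states.sample_ids if s in deg_calls.columns]
    if not samples:
        raise ValueError("state matrix and DEG matrix share no samples")
    records = []
    for protein in mr_states.protein_ids:
        state_vec = mr_states.values.loc[protein, samples].to_numpy()
        if protein not in deg_calls.index:
            logger.info("MR %s has no measured encoding gene; unselected", protein)
            records.append(
                FeedbackRecord(protein, np.nan, np.nan, np.nan, False, "gene not measured")
            )
            continue
        deg_vec = deg_calls.loc[protein, samples].to_numpy()
        cos = cosine(state_vec, deg_vec)
        ci_low, ci_high = bootstrap_ci(
            state_vec, deg_vec, n_boot=n_boot, level=level,
            seed=subseed(seed, "feedback", protein),
        )
        selected = bool(cos > cos_threshold and ci_low > 0)
        records.append(FeedbackRecord(protein, cos, ci_low, ci_high, selected))
    return records


def feedback_table(records: list[FeedbackRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "cosine": [r.cosine for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "selected": [r.selected for r in records],
            "reason": [r.reason for r in records],
        }
    )


def merged_scores(mr_states: StateMatrix, deg_calls: pd.DataFrame) -> pd.DataFrame:
    """Merge state and DEG call into a single -3..3 score per protein/sample.

    |3|: state and call agree in sign; |2|: state nonzero, call 0;
    |1|: state 0, call nonzero; 0 otherwise (including sign conflicts).
    """
    samples = [s for s in mr_states.sample_ids if s in deg_calls.columns]
    state = mr_states.values[samples]
    call = deg_calls.reindex(index=state.index, columns=samples).fillna(0).astype(np.int64)
    s = state.to_numpy()
    c = call.to_numpy()
    score = np.zeros_like(s)
    agree = (s != 0) & (c == s)
    state_only = (s != 0) & (c == 0)
    call_only = (s == 0) & (c != 0)
    score[agree] = 3 * s[agree]
    score[state_only] = 2 * s[state_only]
    score[call_only] = c[call_only]
    return pd.DataFrame(score, index=state.index, columns=samples)


def _cosine_distance_matrix(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = mat / safe[:, None]
    sim = unit @ unit.T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def bicluster(matrix: pd.DataFrame) -> ClusteringResult:
    """Ward-cluster rows and columns of a merged-score matrix.

    Distances are 1 - cosine (zero vectors at distance 1 from everything);
    linkage follows the Lance-Williams Ward update on the distance matrix
    (the ward.D2 convention). Deterministic on identical input.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to bicluster")
    values = matrix.to_numpy(dtype=float)
    if not values.any():
        raise ValueError("all-zero matrix: cosine distances are degenerate")
    row_link = linkage(squareform(_cosine_distance_matrix(values), checks=False), method="ward")
    col_link = linkage(squareform(_cosine_distance_matrix(values.T), checks=False), method="ward")
    return ClusteringResult(
        row_order=[int(i) for i in leaves_list(row_link)],
        col_order=[int(i) for i in leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
    )


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = to_tree(link)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    # root branch length 0
    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def subtype_containment(
    mr_presence: pd.DataFrame, subtype_labels: pd.Series
) -> pd.DataFrame:
    """Fraction of subtype A's regulators also found in subtype B.

    ``mr_presence`` is a boolean protein x sample matrix; a regulator
    belongs to a subtype when present in at least one of its samples.
    Entry (A, B) is |S_A intersect S_B| / |S_A| (NaN when S_A is empty).
    """
    labels = pd.Series(subtype_labels)
    subtypes = sorted(labels.unique())
    sets = {}
    for st in subtypes:
        cols = [c for c in mr_presence.columns if labels.get(c) == st]
        present = mr_presence[cols].any(axis=1)
        sets[st] = set(present.index[present])
    out = pd.DataFrame(index=subtypes, columns=subtypes, dtype=float)
    for a in subtypes:
        for b in subtypes:
            out.loc[a, b] = (
                len(sets[a] & sets[b]) / len(sets[a]) if sets[a] else np.nan
            )
    return out
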