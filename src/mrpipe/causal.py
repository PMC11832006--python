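"""Signed shortest-path causal reasoning for upstream master regulators.

Given a directed signed signaling network and the observed discrete TF
states of one sample, every network node is evaluated as a hypothesis
"this node is active (+1) / inactive (-1)". The predicted effect of a
hypothesis on a TF is the hypothesis sign times the sign product along the
shortest directed path(s) to that TF; TFs reached by equally short paths
with conflicting sign products are non-informative (ambiguous). The score
of a hypothesis is (#explained - #contradicted) TF observations, and its
significance is assessed by a permutation test that reassigns the observed
state multiset across the observed TF positions. Hypotheses are evaluated
at path-length limits delta = 1..depth and merged; nodes called active at
one delta and inactive at another are controversial and dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from ._seeds import subseed
from .data_io import SignedNetwork, StateMatrix

logger = logging.getLogger(__name__)

AMBIGUOUS = 0  #: sentinel for conflicting shortest-path sign products


@dataclass
class SignedReach:
    """Shortest-path distances and sign products from one source node.

    ``signs[node]`` is +1 or -1 when every shortest path from the source
    carries the same sign product, :data:`AMBIGUOUS` otherwise. The source
    itself is at distance 0 with sign +1.
    """

    source: str
    distances: dict[str, int]
    signs: dict[str, int]

    def restrict(self, delta: int) -> "SignedReach":
        keep = {n for n, d in self.distances.items() if d <= delta}
        return SignedReach(
            source=self.source,
            distances={n: self.distances[n] for n in keep},
            signs={n: self.signs[n] for n in keep},
        )


@dataclass
class HypothesisScore:
    node: str
    sign: int
    delta: int
    score: int
    n_explained: int
    n_contradicted: int
    n_ambiguous: int
    p_value: float


def signed_shortest_paths(network: SignedNetwork, source: str, delta: int) -> SignedReach:
    """Breadth-first signed reachability from ``source`` up to depth ``delta``."""
    if source not in network.nodes:
        raise ValueError(f"source {source!r} not in network")
    distances = {source: 0}
    sign_sets: dict[str, frozenset] = {source: frozenset({1})}
    frontier = [source]
    for depth in range(1, delta + 1):
        level: dict[str, set] = {}
        for node in frontier:
            for target, edge_sign in network.successors(node):
                if target in distances:
                    continue  # reached strictly earlier
                acc = level.setdefault(target, set())
                acc.update(s * edge_sign for s in sign_sets[node])
        for target, signs in level.items():
            distances[target] = depth
            sign_sets[target] = frozenset(signs)
        frontier = list(level)
        if not frontier:
            break
    signs = {
        node: (next(iter(s)) if len(s) == 1 else AMBIGUOUS)
        for node, s in sign_sets.items()
    }
    return SignedReach(source=source, distances=distances, signs=signs)


def score_hypothesis(
    reach: SignedReach, observations: Mapping[str, int], hypothesis_sign: int
) -> HypothesisScore:
    """Score the hypothesis ``reach.source`` has state ``hypothesis_sign``.

    ``observations`` maps observed TFs to their states (+1/-1). An observed
    TF reached with an unambiguous sign sigma predicts state
    ``hypothesis_sign * sigma``; matches count as explained, mismatches as
    contradicted, ambiguous/unreachable TFs as non-informative.
    """
    if not observations:
        raise ValueError("observations must be nonempty")
    if hypothesis_sign not in (1, -1):
        raise ValueError("hypothesis sign must be +1 or -1")
    explained = contradicted = ambiguous = 0
    for tf, observed in observations.items():
        sigma = reach.signs.get(tf)
        if sigma is None or sigma == AMBIGUOUS:
            ambiguous += 1
            continue
        prediction = hypothesis_sign * sigma
        if prediction == observed:
            explained += 1
        else:
            contradicted += 1
    return HypothesisScore(
        node=reach.source,
        sign=hypothesis_sign,
        delta=max(reach.distances.values(), default=0),
        score=explained - contradicted,
        n_explained=explained,
        n_contradicted=contradicted,
        n_ambiguous=ambiguous,
        p_value=float("nan"),
    )


def _predictions(reach: SignedReach, tf_order: list[str], hypothesis_sign: int) -> np.ndarray:
    """Predicted states over observed TF positions; 0 for non-informative."""
    preds = np.zeros(len(tf_order), dtype=np.int64)
    for i, tf in enumerate(tf_order):
        sigma = reach.signs.get(tf)
        if sigma is not None and sigma != AMBIGUOUS:
            preds[i] = hypothesis_sign * sigma
    return preds


def permutation_pvalue(
    reach: SignedReach,
    observations: Mapping[str, int],
    hypothesis_sign: int,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive_limit: int = 10**4,
) -> float:
    """Permutation p-value for a hypothesis score.

    The null reassigns the observed state multiset uniformly at random
    across the observed TF positions. When the number of distinct
    assignments (n choose #positive) does not exceed ``exhaustive_limit``
    the null is enumerated exhaustively and p = #{score >= observed}/total;
    otherwise p = (1 + #{score >= observed})/(1 + n_perm) over Monte-Carlo
    draws.
    """
    tf_order = list(observations)
    obs = np.array([observations[t] for t in tf_order], dtype=np.int64)
    preds = _predictions(reach, tf_order, hypothesis_sign)
    observed_score = int(preds @ obs)
    n = len(obs)
    n_plus = int((obs == 1).sum())
    total = comb(n, n_plus)
    if total <= exhaustive_limit:
        count = 0
        for plus_positions in combinations(range(n), n_plus):
            assignment = -np.ones(n, dtype=np.int64)
            assignment[list(plus_positions)] = 1
            if preds @ assignment >= observed_score:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(obs, (n_perm, 1)), axis=1)
    scores = perms @ preds
    return float((1 + (scores >= observed_score).sum()) / (1 + n_perm))


def call_mrs_per_sample(
    network: SignedNetwork,
    tf_states: Mapping[str, int],
    delta_max: int = 3,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    adjust: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Call master regulators for one sample from its nonzero TF states.

    Every network node is scored as an active/inactive hypothesis at each
    delta in 1..delta_max; calls significant at some delta (p < alpha and
    score > 0) are merged by union. Nodes significant with opposite signs
    at different deltas are controversial and removed. Returns the calls
    (node -> +1/-1) and the full hypothesis table.
    """
    observations = {tf: int(s) for tf, s in tf_states.items() if s != 0}
    if not observations:
        return pd.Series(dtype=np.int64), pd.DataFrame()
    rows = []
    calls: dict[str, set[int]] = {}
    pvals: list[float] = []
    for node in sorted(network.nodes):
        reach_full = signed_shortest_paths(network, node, delta_max)
        for delta in range(1, delta_max + 1):
            reach = reach_full.restrict(delta)
            for sign in (1, -1):
                hs = score_hypothesis(reach, observations, sign)
                hs.delta = delta
                hs.p_value = permutation_pvalue(
                    reach,
                    observations,
                    sign,
                    n_perm=n_perm,
                    seed=subseed(seed, node, delta, sign),
                )
                rows.append(hs)
                pvals.append(hs.p_value)
    if adjust:
        from .diffexpr import bh_adjust

        adjusted = bh_adjust(np.array(pvals))
    else:
        adjusted = np.array(pvals)
    for hs, p_eff in zip(rows, adjusted):
        if hs.score > 0 and p_eff < alpha:
            calls.setdefault(hs.node, set()).add(hs.sign)
    merged = {}
    for node, signs in calls.items():
        if len(signs) == 1:
            merged[node] = signs.pop()
        else:
            logger.info("node %s controversial (both signs significant); removed", node)
    table = pd.DataFrame(
        {
            "node": [h.node for h in rows],
            "sign": [h.sign for h in rows],
            "delta": [h.delta for h in rows],
            "score": [h.score for h in rows],
            "n_explained": [h.n_explained for h in rows],
            "n_contradicted": [h.n_contradicted for h in rows],
            "n_ambiguous": [h.n_ambiguous for h in rows],
            "p_value": [h.p_value for h in rows],
        }
    )
    return pd.Series(merged, dtype=np.int64).sort_index(), table


def call_mrs(
    network: SignedNetwork,
    tf_states: StateMatrix,
    delta_max: int = 3,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[StateMatrix, dict[str, pd.DataFrame]]:
    """Run :func:`call_mrs_per_sample` for every sample of a TF state matrix."""
    columns = {}
    tables = {}
    for sample in tf_states.sample_ids:
        states = tf_states.values[sample]
        calls, table = call_mrs_per_sample(
            network,
            states.to_dict(),
            delta_max=delta_max,
            alpha=alpha,
            n_perm=n_perm,
            seed=subseed(seed, "sample", sample),
        )
        columns[sample] = calls
        tables[sample] = table
    values = (
        pd.DataFrame(columns)
        .reindex(columns=tf_states.sample_ids)
        .fillna(0)
        .astype(np.int64)
        .sort_index()
    )
    return StateMatrix(values=values, tag="MR"), tables
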