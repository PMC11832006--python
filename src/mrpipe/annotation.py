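"""Over-representation, immune-score correlation and single-cell summaries.

Pathway over-representation uses the one-sided hypergeometric upper tail
against a user-supplied universe, with the pipeline's filter (at least two
regulator genes in the set and raw p < 0.05). The immune infiltration
score is a single-sample rank-weighted enrichment of an immune signature
in each bulk profile. The dual-level Kendall screen marks a regulator as
infiltration-correlated only when both its discrete state vector and its
gene's expression correlate positively and significantly with the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GeneSetCollection, SingleCellMatrix
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class CorrelationRecord:
    protein: str
    tau_discrete: float
    tau_expression: float
    p_discrete: float
    p_expression: float
    correlated: bool


def ora_enrich(
    query_genes: list[str],
    universe: list[str],
    gene_sets: GeneSetCollection,
    min_overlap: int = 2,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene list.

    Sets are restricted to the universe; query genes outside the universe
    are dropped with a log message. ``passes_filter`` requires at least
    ``min_overlap`` query genes in the set and raw p < ``p_threshold``.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_genes)
    outside = query - universe_set
    if outside:
        logger.info("%d query genes outside the universe dropped", len(outside))
        query &= universe_set
    n_universe = len(universe_set)
    n_query = len(query)
    rows = []
    for name, (description, members) in gene_sets.items():
        members_in = set(members) & universe_set
        n_set = len(members_in)
        n_overlap = len(members_in & query)
        if n_set == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set, n_query))
        rows.append((name, description, n_overlap, n_set, n_query, n_universe, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "set_name", "description", "n_overlap", "n_set",
            "n_query", "n_universe", "p_value",
        ],
    )
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    table["passes_filter"] = (table["n_overlap"] >= min_overlap) & (
        table["p_value"] < p_threshold
    )
    return table


def immune_score(
    expression: pd.DataFrame,
    signature: list[str],
    exponent: float = 0.25,
    min_signature: int = 10,
) -> pd.Series:
    """Single-sample rank-weighted enrichment score of a signature.

    Per sample, genes are ranked by expression; the score is the summed
    difference between the rank-weighted (rank**exponent) cumulative
    distribution of signature genes and the unweighted cumulative
    distribution of the remainder, walking the ranking from the most to
    the least expressed gene. A rank statistic: invariant under strictly
    monotone transforms of the expression column.
    """
    in_sig = expression.index.isin(set(signature))
    n_in = int(in_sig.sum())
    if n_in < min_signature:
        raise ValueError(
            f"only {n_in} signature genes measured (< {min_signature})"
        )
    n = expression.shape[0]
    scores = {}
    for sample in expression.columns:
        x = expression[sample].to_numpy(dtype=float)
        order = np.argsort(-x, kind="stable")  # most expressed first
        sig_sorted = in_sig[order]
        ranks = np.arange(n, 0, -1, dtype=float)  # rank n for the top gene
        weights = np.where(sig_sorted, ranks**exponent, 0.0)
        cdf_in = np.cumsum(weights)
        cdf_in /= cdf_in[-1] if cdf_in[-1] > 0 else 1.0
        out = (~sig_sorted).astype(float)
        cdf_out = np.cumsum(out)
        cdf_out /= cdf_out[-1] if cdf_out[-1] > 0 else 1.0
        scores[sample] = float((cdf_in - cdf_out).sum())
    return pd.Series(scores)


def kendall_screen(
    states: pd.Series,
    expression: pd.Series,
    scores: pd.Series,
    protein: str = "",
    alpha: float = 0.05,
) -> CorrelationRecord:
    """Dual-level Kendall screen of one regulator against immune scores.

    ``correlated`` requires positive tau with p < alpha at BOTH the
    discrete-state level and the expression level. Constant inputs give an
    undefined tau and an automatic ``correlated=False`` (logged).
    """
    samples = scores.index
    x_disc = states.reindex(samples).to_numpy(dtype=float)
    x_expr = expression.reindex(samples).to_numpy(dtype=float)
    y = scores.to_numpy(dtype=float)

    def tau_of(x: np.ndarray) -> tuple[float, float]:
        if np.unique(x[~np.isnan(x)]).size < 2 or np.unique(y).size < 2:
            logger.info("constant vector for %s: tau undefined", protein or "<protein>")
            return float("nan"), float("nan")
        result = stats.kendalltau(x, y, variant="b")
        return float(result.statistic), float(result.pvalue)

    tau_d, p_d = tau_of(x_disc)
    tau_e, p_e = tau_of(x_expr)
    correlated = bool(
        np.isfinite(tau_d) and np.isfinite(tau_e)
        and tau_d > 0 and tau_e > 0 and p_d < alpha and p_e < alpha
    )
    return CorrelationRecord(protein, tau_d, tau_e, p_d, p_e, correlated)


def kendall_screen_all(
    mr_states: pd.DataFrame,
    expression: pd.DataFrame,
    scores: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the dual-level Kendall screen for every regulator with a gene."""
    rows = []
    for protein in mr_states.index:
        if protein not in expression.index:
            rows.append(CorrelationRecord(protein, np.nan, np.nan, np.nan, np.nan, False))
            continue
        rows.append(
            kendall_screen(
                mr_states.loc[protein], expression.loc[protein], scores,
                protein=protein, alpha=alpha,
            )
        )
    return pd.DataFrame(
        {
            "protein": [r.protein for r in rows],
            "tau_discrete": [r.tau_discrete for r in rows],
            "tau_expression": [r.tau_expression for r in rows],
            "p_discrete": [r.p_discrete for r in rows],
            "p_expression": [r.p_expression for r in rows],
            "correlated": [r.correlated for r in rows],
        }
    )


def single_cell_summary(
    sc: SingleCellMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean tpm and percent of expressing cells per gene and cell type.

    Returns the summary (MultiIndex columns (cell_type, statistic)) and a
    decile-bin histogram of pct_nonzero per cell type (bins [0,10), ...,
    [90,100]).
    """
    cell_types = sorted(sc.cell_types.unique())
    blocks = {}
    for ct in cell_types:
        cells = sc.cell_types.index[sc.cell_types == ct]
        if len(cells) == 0:
            raise ValueError(f"cell type {ct!r} has no cells")
        sub = sc.tpm[cells]
        blocks[(ct, "mean_tpm")] = sub.mean(axis=1)
        blocks[(ct, "pct_nonzero")] = 100.0 * (sub > 0).sum(axis=1) / len(cells)
    summary = pd.DataFrame(blocks)
    summary.columns = pd.MultiIndex.from_tuples(summary.columns)
    edges = np.arange(0, 101, 10)
    hist = {}
    for ct in cell_types:
        pct = summary[(ct, "pct_nonzero")].to_numpy()
        # numpy closes the final bin, so [90, 100] includes exact 100s
        counts, _ = np.histogram(pct, bins=edges)
        hist[ct] = counts
    bins = pd.DataFrame(
        hist, index=[f"[{a},{b}{']' if b == 100 else ')'}" for a, b in zip(edges[:-1], edges[1:])]
    )
    return summary, bins
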