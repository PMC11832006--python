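"""TF activity from signed regulon enrichment on logFC signatures.

The signature's logFC values are converted to fractional ranks and mapped
through the standard normal quantile function; a TF's normalized
enrichment score (NES) is the mode-weighted sum of its targets' z-values
scaled by the square root of the regulon size, which is standard normal
under a label-permutation null. Positive NES with small adjusted p means
the TF's activity increase explains the signature ("active"), negative
NES means an activity decrease would ("inactive").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .data_io import RegulonSet, StateMatrix
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ActivityCall:
    tf: str
    nes: float
    p_value: float
    p_adjusted: float
    state: int


def signature_zscores(logfc: pd.Series) -> pd.Series:
    """Fractional-rank normal scores of a logFC signature (ties averaged)."""
    ranks = logfc.rank(method="average")
    r = (ranks - 0.5) / len(logfc)
    return pd.Series(ndtri(r.to_numpy()), index=logfc.index)


def score_regulon(
    signature: pd.Series,
    regulon: dict[str, int],
    min_targets: int = 5,
    zscores: pd.Series | None = None,
) -> tuple[float, float] | None:
    """NES and two-sided normal p for one regulon against one signature.

    Returns None (logged) when fewer than ``min_targets`` regulon targets
    are measured in the signature.
    """
    if zscores is None:
        zscores = signature_zscores(signature)
    measured = [g for g in regulon if g in zscores.index]
    if len(measured) < min_targets:
        logger.info(
            "regulon skipped: only %d of %d targets measured (< %d)",
            len(measured), len(regulon), min_targets,
        )
        return None
    modes = np.array([regulon[g] for g in measured], dtype=float)
    z = zscores[measured].to_numpy()
    nes = float((modes * z).sum() / sqrt(len(measured)))
    p = float(2.0 * ndtr(-abs(nes)))
    return nes, p


def score_all_regulons(
    signature: pd.Series, regulons: RegulonSet, min_targets: int = 5
) -> pd.DataFrame:
    """NES/p table for every scorable TF of one sample signature."""
    zscores = signature_zscores(signature)
    rows = {}
    for tf in regulons.tf_ids:
        result = score_regulon(signature, regulons[tf], min_targets, zscores=zscores)
        if result is not None:
            rows[tf] = result
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["nes", "p_value"])
    table.index.name = "tf"
    return table


def call_tf_states(
    scores: dict[str, pd.DataFrame], alpha: float = 0.05
) -> tuple[StateMatrix, pd.DataFrame]:
    """Binarize per-sample NES tables into a TF x sample state matrix.

    p-values are BH-adjusted across TFs within each sample; a TF is active
    (+1) when NES > 0 and adjusted p < alpha, inactive (-1) when NES < 0
    and adjusted p < alpha, and 0 otherwise.
    """
    if not scores:
        raise ValueError("no samples scored")
    columns = {}
    records = []
    for sample, table in scores.items():
        if table.empty:
            columns[sample] = pd.Series(dtype=np.int64)
            continue
        p_adj = bh_adjust(table["p_value"].to_numpy())
        nes = table["nes"].to_numpy()
        state = np.where(p_adj < alpha, np.sign(nes), 0).astype(np.int64)
        columns[sample] = pd.Series(state, index=table.index)
        for tf, n, p, pa, s in zip(table.index, nes, table["p_value"], p_adj, state):
            records.append((sample, tf, n, p, pa, s))
    values = pd.DataFrame(columns).fillna(0).astype(np.int64).sort_index()
    calls = pd.DataFrame(
        records, columns=["sample", "tf", "nes", "p_value", "p_adjusted", "state"]
    )
    return StateMatrix(values=values, tag="TF"), calls


def infer_tf_activity(
    signatures: dict[str, pd.DataFrame],
    regulons: RegulonSet,
    alpha: float = 0.05,
    min_targets: int = 5,
) -> tuple[StateMatrix, pd.DataFrame]:
    """Full TF-activity stage: score every sample signature and binarize."""
    scores = {
        sample: score_all_regulons(sig["logFC"], regulons, min_targets)
        for sample, sig in signatures.items()
    }
    return call_tf_states(scores, alpha=alpha)
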