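"""Per-sample differential expression against a reference group.

Each tumor sample is compared on its own to the reference samples: the
log2 fold change is taken against the mean normalized reference count, and
the tumor count is tested as a negative-binomial outlier of the reference
distribution. Calls are discretized with the |logFC| > 1, BH-adjusted
p < 0.05 convention.

The per-gene dispersion is a method-of-moments estimate from the reference
samples shrunk toward a pooled common dispersion; the test dispersion
additionally folds in the sampling variance of the estimated reference
mean (with a handful of reference samples the plug-in test would otherwise
be anti-conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEConfig:
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    pseudocount: float = 0.5
    dispersion_shrink: float = 0.8  # weight toward the common dispersion

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.pseudocount <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.dispersion_shrink <= 1:
            raise ValueError("dispersion_shrink must be in [0, 1]")


def filter_low_expression(
    counts: CountMatrix, size_factors: pd.Series | None = None
) -> CountMatrix:
    """Drop genes whose mean normalized count falls below the lower quartile.

    The threshold is the 25th percentile (linear interpolation) of all gene
    means; the comparison is strict, so ties at the threshold survive.
    """
    if len(counts.gene_ids) < 4:
        raise ValueError("need at least 4 genes to apply the quartile filter")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    normalized = counts.counts / size_factors
    means = normalized.mean(axis=1)
    threshold = float(np.percentile(means.to_numpy(), 25))
    survivors = [g for g in counts.gene_ids if means[g] >= threshold]
    if not survivors:
        raise ValueError("quartile filter removed every gene")
    return counts.subset_genes(survivors)


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    The pseudo-reference is the per-gene geometric mean over genes with
    all-positive counts; when no such gene exists the factors fall back to
    library sizes (logged).
    """
    mat = counts.counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logs = np.log(mat[positive])
        pseudo = logs.mean(axis=1, keepdims=True)
        ratios = logs - pseudo
        log_factors = np.median(ratios, axis=0)
    else:
        logger.warning("no gene positive in all samples; using library-size factors")
        lib = counts.library_sizes.to_numpy(dtype=float)
        if (lib <= 0).any():
            raise ValueError("cannot derive size factors: empty library")
        log_factors = np.log(lib)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.sample_ids)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _nb_two_sided_pvalue(k: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Two-sided NB tail probability including the observed point mass.

    p = min(1, 2*min(P(X <= k), P(X >= k))); Poisson at phi ~ 0. The
    doubling convention is explicit because discreteness makes "two-sided"
    ambiguous.
    """
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    lower = np.empty_like(mu)
    upper = np.empty_like(mu)
    poisson_like = phi < 1e-12
    if poisson_like.any():
        lower[poisson_like] = stats.poisson.cdf(k[poisson_like], mu[poisson_like])
        upper[poisson_like] = stats.poisson.sf(k[poisson_like] - 1, mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        size = 1.0 / phi[nb]
        prob = size / (size + mu[nb])
        lower[nb] = stats.nbinom.cdf(k[nb], size, prob)
        upper[nb] = stats.nbinom.sf(k[nb] - 1, size, prob)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def call_degs_per_sample(
    counts: CountMatrix,
    sample_id: str,
    config: DEConfig = DEConfig(),
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Differential-expression signature of one tumor sample vs the references.

    Returns a per-gene table with columns logFC, p_value, p_adjusted and
    call in {-1, 0, +1}.
    """
    if counts.roles.get(sample_id) != "tumor":
        raise ValueError(f"sample {sample_id!r} is not a tumor sample")
    refs = counts.reference_ids
    if len(refs) < 2:
        raise ValueError("need at least 2 reference samples")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    f_s = float(size_factors[sample_id])
    norm_ref = counts.counts[refs].to_numpy(dtype=float) / size_factors[refs].to_numpy()
    m = norm_ref.mean(axis=1)
    v = norm_ref.var(axis=1, ddof=1)
    n_ref = len(refs)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(m > 0, (v - m) / np.square(m), 0.0)
    phi_raw = np.clip(phi_raw, 0.0, None)
    denom = float(np.square(m).sum())
    phi_common = max(0.0, float((v - m).sum()) / denom) if denom > 0 else 0.0
    w = config.dispersion_shrink
    phi = (1 - w) * phi_raw + w * phi_common
    # fold in the sampling variance of the estimated reference mean
    m_safe = np.maximum(m, 0.5 / n_ref)
    phi_test = phi * (1.0 + 1.0 / n_ref) + 1.0 / (n_ref * m_safe)

    k = counts.counts[sample_id].to_numpy(dtype=float)
    c = config.pseudocount
    logfc = np.log2((k / f_s + c) / (m + c))
    mu = m_safe * f_s
    p = _nb_two_sided_pvalue(k, mu, phi_test)
    p_adj = bh_adjust(p)
    call = np.where(
        (p_adj < config.alpha) & (np.abs(logfc) > config.lfc_threshold),
        np.sign(logfc),
        0,
    ).astype(np.int64)
    return pd.DataFrame(
        {"logFC": logfc, "p_value": p, "p_adjusted": p_adj, "call": call},
        index=counts.gene_ids,
    )


def call_all_degs(
    counts: CountMatrix,
    config: DEConfig = DEConfig(),
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Signatures for every tumor sample plus the combined discrete DEG matrix."""
    size_factors = estimate_size_factors(counts)
    signatures = {
        s: call_degs_per_sample(counts, s, config, size_factors)
        for s in counts.tumor_ids
    }
    deg_matrix = pd.DataFrame(
        {s: sig["call"] for s, sig in signatures.items()}
    ).astype(np.int64)
    return signatures, deg_matrix
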