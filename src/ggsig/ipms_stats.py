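"""Interactor calling from IP-MS spectral counts.

Spectral counts (number of MS/MS spectra per protein) are normalised
across samples by the median-of-ratios method: each sample's size factor
is the median, over proteins with a positive geometric mean, of the ratio
of that sample's count to the protein's geometric mean.  Enrichment in
the bait IP versus the knockout-control IP is tested per protein with a
two-group negative-binomial exact-style test: a common dispersion is
estimated by method of moments across proteins, and the split of the two
group sums conditioned on their total follows a negative hypergeometric
law that is free of the unknown mean.  In the zero-dispersion limit this
reduces to the conditional binomial (exact Poisson) test.  Fold changes
come from normalised group means with a 0.5 pseudocount; p-values are
Benjamini-Hochberg adjusted.  Enriched partners are called at fold
change > 4 and adjusted p-value < 0.05 (both strict).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .geneset_stats import bh_adjust

logger = logging.getLogger(__name__)

FC_MIN = 4.0
PADJ_MAX = 0.05
LOG2FC_PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq2-style median-of-ratios size factors per sample (column)."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no protein has positive counts in every sample; "
            "supply a pseudo-reference subset of consistently detected proteins"
        )
    log_ref = np.log(mat[positive]).mean(axis=1)  # log geometric mean per protein
    log_ratios = np.log(mat[positive]) - log_ref[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_common_dispersion(
    normalized: np.ndarray, group_index: list[np.ndarray]
) -> float:
    """Pooled method-of-moments NB dispersion across proteins.

    For NB counts, Var = mu + phi * mu^2; phi is estimated by pooling
    (sample variance - mean) against mean^2 over all protein/group cells
    with at least two samples, clipped at 0 (Poisson limit).
    """
    num = 0.0
    den = 0.0
    for idx in group_index:
        if len(idx) < 2:
            continue
        sub = normalized[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        keep = m > 0
        num += w * float(np.sum(v[keep] - m[keep]))
        den += w * float(np.sum(m[keep] ** 2))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _exact_conditional_pvalue(s_num: int, s_den: int, n_num: int, n_den: int, phi: float) -> float:
    """Two-sided exact-style p for the split of two NB group sums given their total.

    With common dispersion phi the group sums are NB with sizes n/phi and
    a shared success probability, so the conditional law of one sum given
    the total is negative hypergeometric; phi -> 0 gives the binomial
    with probability n_num / (n_num + n_den).  Two-sided p sums all
    conditional outcomes no more probable than the observed one.
    """
    t = s_num + s_den
    if t == 0:
        return 1.0
    s = np.arange(t + 1)
    if phi <= 0:
        logw = binom.logpmf(s, t, n_num / (n_num + n_den))
    else:
        r_num, r_den = n_num / phi, n_den / phi
        logw = (
            gammaln(s + r_num) - gammaln(s + 1) - gammaln(r_num)
            + gammaln(t - s + r_den) - gammaln(t - s + 1) - gammaln(r_den)
        )
        logw -= logsumexp(logw)
    obs = logw[s_num]
    tail = logw[logw <= obs + 1e-9]
    return float(min(1.0, np.exp(logsumexp(tail))))


def nb_test(
    counts: pd.DataFrame,
    group_labels,
    numerator: str,
    denominator: str,
    factors: pd.Series | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-protein NB two-group test of *numerator* vs *denominator* samples.

    ``group_labels`` aligns with the columns of ``counts``.  Counts are
    divided by median-of-ratios size factors (supplied or recomputed),
    a common dispersion is moment-estimated across proteins unless given,
    and each protein's group sums are compared with the conditioned
    exact-style test.  All-zero proteins are excluded and logged.
    Returns (protein, base_mean, log2fc, pvalue, padj) sorted by pvalue.
    """
    labels = pd.Series(list(group_labels), index=counts.columns)
    for g in (numerator, denominator):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]

    nonzero = norm.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("nb_test: %d all-zero proteins excluded", n_dropped)
    norm = norm[nonzero]
    proteins = counts.index[nonzero]

    idx_num = np.flatnonzero((labels == numerator).to_numpy())
    idx_den = np.flatnonzero((labels == denominator).to_numpy())
    if dispersion is None:
        dispersion = estimate_common_dispersion(norm, [idx_num, idx_den])

    m_num = norm[:, idx_num].mean(axis=1)
    m_den = norm[:, idx_den].mean(axis=1)
    log2fc = np.log2((m_num + LOG2FC_PSEUDOCOUNT) / (m_den + LOG2FC_PSEUDOCOUNT))

    s_num = np.rint(norm[:, idx_num].sum(axis=1)).astype(int)
    s_den = np.rint(norm[:, idx_den].sum(axis=1)).astype(int)
    pvals = np.array(
        [
            _exact_conditional_pvalue(a, b, len(idx_num), len(idx_den), dispersion)
            for a, b in zip(s_num, s_den)
        ]
    )
    out = pd.DataFrame(
        {
            "protein": proteins,
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        }
    )
    out.attrs["dispersion"] = float(dispersion)
    return out.sort_values(["pvalue", "protein"], kind="mergesort").reset_index(drop=True)


def call_interactors(
    stats: pd.DataFrame, fc_min: float = FC_MIN, padj_max: float = PADJ_MAX
) -> set[str]:
    """Enriched partners: linear fold change > fc_min and padj < padj_max, strictly."""
    fc = np.power(2.0, stats["log2fc"].astype(float))
    mask = (fc > fc_min) & (stats["padj"] < padj_max)
    return set(stats.loc[mask, "protein"])
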