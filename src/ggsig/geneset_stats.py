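"""Gene-set statistics: hypergeometric enrichment, BH adjustment, DE filters, FPKM.

The enrichment of a query gene list in an annotation term is tested with
the upper-tail hypergeometric probability P(X >= k) of drawing k term
members in a query of size n from a universe of N genes containing K term
members; p-values across terms are adjusted with the Benjamini-Hochberg
step-up procedure.  Differential-expression calls use strict thresholds
on the linear fold change and adjusted p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    @classmethod
    def of(cls, name: str, members) -> "GeneSet":
        return cls(name, frozenset(members))


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts term members among ``n`` draws without replacement from a
    universe of ``N`` genes of which ``K`` belong to the term.  Computed
    from the log survival function for stability in deep tails.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N:
        raise ValueError(f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(np.exp(hypergeom.logsf(k - 1, N, K, n)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: GeneSet, terms: list[GeneSet], universe: GeneSet
) -> pd.DataFrame:
    """Hypergeometric enrichment of *query* in each term, BH across terms."""
    if not universe.members:
        raise ValueError("empty universe")
    uni = universe.members
    q = query.members & uni
    dropped = len(query.members) - len(q)
    if dropped:
        logger.warning("enrich: %d query genes outside universe dropped", dropped)
    N, n = len(uni), len(q)
    rows = []
    for term in terms:
        t = term.members & uni
        K = len(t)
        k = len(q & t)
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        p = hypergeom_upper(k, n, K, N) if K > 0 else 1.0
        rows.append((term.name, k, n, K, N, fold, p))
    df = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "fold_enrichment", "pvalue"]
    )
    df["padj"] = bh_adjust(df["pvalue"].to_numpy()) if len(df) else []
    return df.sort_values(["pvalue", "term"], kind="mergesort").reset_index(drop=True)


def de_filter(
    stats: pd.DataFrame,
    fc_min: float,
    padj_max: float,
    log2fc_col: str = "log2fc",
    padj_col: str = "padj",
    gene_col: str = "gene",
) -> tuple[set[str], set[str]]:
    """Split genes into up/down sets by strict fold-change and padj thresholds.

    Fold change is compared on the linear scale: up requires
    ``fold change > fc_min``; down requires ``fold change < 1/fc_min``.
    Rows with missing padj are treated as not significant.
    """
    if fc_min <= 1:
        raise ValueError("fc_min must exceed 1")
    for col in (log2fc_col, padj_col, gene_col):
        if col not in stats.columns:
            raise ValueError(f"missing column {col!r}")
    padj = stats[padj_col]
    n_missing = int(padj.isna().sum())
    if n_missing:
        logger.warning("de_filter: %d rows with missing padj treated as NS", n_missing)
    fc = np.power(2.0, stats[log2fc_col].astype(float))
    sig = padj.notna() & (padj < padj_max)
    up = set(stats.loc[sig & (fc > fc_min), gene_col])
    down = set(stats.loc[sig & (fc < 1.0 / fc_min), gene_col])
    return up, down


def fpkm(
    counts: pd.DataFrame, gene_lengths_bp: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Fragments per kilobase per million: counts / (length_kb * libsize_M)."""
    lengths = gene_lengths_bp.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing gene lengths for {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive for all samples")
    return counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


def read_gmt(path: str) -> list[GeneSet]:
    """Read GMT term files: term <tab> description <tab> member..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            sets.append(GeneSet.of(f[0], [g for g in f[2:] if g]))
    return sets


def venn_overlap_test(
    set_a: set[str], set_b: set[str], universe_size: int
) -> tuple[int, float]:
    """Overlap count and hypergeometric p-value for a two-set Venn comparison."""
    k = len(set_a & set_b)
    return k, hypergeom_upper(k, len(set_a), len(set_b), universe_size)
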