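"""Candidate hit selection from pooled CRISPR knockout screen summaries.

Operates on MAGeCK-style per-gene positive-selection summaries (score,
p-value, rank; lower rank = stronger enrichment in the sorted population).
The selection chain is, in order:

1. remove olfactory receptor genes from every table;
2. take the 100 best-ranked genes of the full (all-replicates) analysis
   with positive-selection p-value < 0.05;
3. add the 20 best-ranked genes of each pairwise (two-replicate) analysis;
4. remove genes with expression FPKM < 5 in wild-type cells.

Each removal is logged with the stage and reason; surviving genes carry
provenance describing which table(s) contributed them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_P_MAX = 0.05
DEFAULT_TOP_FULL = 100
DEFAULT_TOP_PAIRWISE = 20
DEFAULT_FPKM_MIN = 5.0
OLFACTORY_PREFIX = "Olfr"


@dataclass
class GeneSummaryTable:
    """Per-gene positive-selection statistics for one screen analysis."""

    analysis_id: str
    table: pd.DataFrame  # columns: gene, pos_score, pos_pvalue, pos_rank

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene", "pos_score", "pos_pvalue", "pos_rank"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"{self.analysis_id}: missing columns {sorted(missing)}")
        if t["gene"].duplicated().any():
            dups = t.loc[t["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"{self.analysis_id}: duplicate gene rows {dups[:5]}")
        ranks = np.sort(t["pos_rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(t) + 1)):
            raise ValueError(f"{self.analysis_id}: ranks are not a permutation of 1..n")
        by_rank = t.sort_values("pos_rank")
        if not by_rank["pos_score"].is_monotonic_increasing:
            raise ValueError(
                f"{self.analysis_id}: pos_rank inconsistent with ascending pos_score"
            )

    def top(self, n: int, p_max: float | None = None) -> pd.DataFrame:
        """Best-ranked *n* genes, optionally restricted to pos_pvalue < p_max."""
        t = self.table
        if p_max is not None:
            t = t[t["pos_pvalue"] < p_max]
        t = t.sort_values(["pos_rank", "pos_score", "gene"], kind="mergesort")
        return t.head(n)

    def drop_genes(self, genes: set[str]) -> "GeneSummaryTable":
        """Remove genes and re-rank the remainder (rank order preserved)."""
        t = self.table[~self.table["gene"].isin(genes)].copy()
        t = t.sort_values(["pos_rank"], kind="mergesort").reset_index(drop=True)
        t["pos_rank"] = np.arange(1, len(t) + 1)
        return GeneSummaryTable(self.analysis_id, t)


def read_gene_summary(path: str, analysis_id: str | None = None) -> GeneSummaryTable:
    """Read a MAGeCK-style gene summary TSV.

    Header names with MAGeCK's pipe style (``pos|score``) are accepted
    and normalised to underscores; ``id`` is accepted for ``gene``.
    """
    df = pd.read_csv(path, sep="\t")
    canonical = {
        "gene": "gene",
        "id": "gene",
        "posscore": "pos_score",
        "pospvalue": "pos_pvalue",
        "posrank": "pos_rank",
    }
    norm = [c.lower().replace("|", "").replace("-", "").replace("_", "") for c in df.columns]
    df.columns = [canonical.get(c, c) for c in norm]
    keep = [c for c in ("gene", "pos_score", "pos_pvalue", "pos_rank") if c in df.columns]
    df = df[keep]
    if analysis_id is None:
        analysis_id = path
    return GeneSummaryTable(analysis_id, df)


@dataclass
class CandidateList:
    """Ordered candidate genes, with provenance and a removal log."""

    genes: list[str]
    provenance: dict[str, list[str]]
    removed: list[tuple[str, str, str]] = field(default_factory=list)  # gene, stage, reason

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "provenance": [";".join(self.provenance[g]) for g in self.genes],
            }
        )

    def removals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["gene", "stage", "reason"])


def olfactory_default(genes, explicit: set[str] | None = None) -> set[str]:
    """Olfactory receptor genes: explicit list if given, else the Olfr prefix."""
    if explicit is not None:
        return set(explicit) & set(genes)
    return {g for g in genes if g.startswith(OLFACTORY_PREFIX)}


def select_candidates(
    full: GeneSummaryTable,
    pairwise: list[GeneSummaryTable],
    fpkm: dict[str, float],
    olfactory: set[str] | None = None,
    p_max: float = DEFAULT_P_MAX,
    top_full: int = DEFAULT_TOP_FULL,
    top_pairwise: int = DEFAULT_TOP_PAIRWISE,
    fpkm_min: float = DEFAULT_FPKM_MIN,
) -> CandidateList:
    """Apply the candidate-selection filter chain to screen summaries.

    ``olfactory`` defaults to the Olfr-prefix rule on the full table's
    genes.  Genes missing from ``fpkm`` are treated as unexpressed (0)
    and logged in the removal list.
    """
    removed: list[tuple[str, str, str]] = []
    all_genes = set(full.table["gene"])
    for pw in pairwise:
        all_genes |= set(pw.table["gene"])
    if olfactory is None:
        olfactory = olfactory_default(all_genes)

    # (1) olfactory genes out of every table before ranking cutoffs apply
    for g in sorted(olfactory & all_genes):
        removed.append((g, "olfactory", "olfactory receptor gene"))
    full_f = full.drop_genes(olfactory)
    pairwise_f = [pw.drop_genes(olfactory) for pw in pairwise]

    provenance: dict[str, list[str]] = {}

    # (2) top genes of the full analysis at p < p_max
    for g in full_f.top(top_full, p_max=p_max)["gene"]:
        provenance.setdefault(g, []).append(f"full_top{top_full}")

    # (3) union with top genes of each pairwise analysis (no p filter)
    for pw in pairwise_f:
        for g in pw.top(top_pairwise)["gene"]:
            provenance.setdefault(g, []).append(
                f"pairwise_top{top_pairwise}:{pw.analysis_id}"
            )

    # (4) expression filter
    survivors = []
    for g in provenance:
        value = fpkm.get(g)
        if value is None:
            removed.append((g, "fpkm", "missing from FPKM table (treated as 0)"))
            continue
        if value < fpkm_min:
            removed.append((g, "fpkm", f"fpkm {value:g} < {fpkm_min:g}"))
            continue
        survivors.append(g)

    full_rank = dict(zip(full_f.table["gene"], full_f.table["pos_rank"]))
    pw_rank: dict[str, int] = {}
    for pw in pairwise_f:
        for g, r in zip(pw.table["gene"], pw.table["pos_rank"]):
            pw_rank[g] = min(pw_rank.get(g, int(r)), int(r))
    survivors.sort(
        key=lambda g: (
            full_rank.get(g, float("inf")),
            pw_rank.get(g, float("inf")),
            g,
        )
    )
    return CandidateList(
        genes=survivors,
        provenance={g: provenance[g] for g in survivors},
        removed=removed,
    )
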