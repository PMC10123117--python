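"""RRBS methylation summarisation.

Per-CpG methylation calls (methylated = unconverted C, unmethylated =
bisulfite-converted T) are merged across strands — a minus-strand call at
position p belongs to the CpG whose plus-strand C sits at p - 1 — by
summing counts and recomputing the ratio from the pooled counts, never by
averaging per-strand ratios.  Sites are filtered at a minimum combined
depth of 8x.  Bisulfite conversion efficiency is estimated from the
cytosines filled in during end repair of MspI (C^CGG) fragment ends,
which are unmethylated by construction: efficiency = T / (T + C).
Region-level methylation is the unweighted mean of site ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEPTH_MIN = 8


def read_coverage(path: str, one_based: bool = False) -> pd.DataFrame:
    """Read a Bismark-coverage-style TSV: chrom, start, end, percent, n_meth, n_unmeth.

    The percent column is recomputed from the counts, never trusted.
    Positions are returned 0-based (set ``one_based`` for 1-based input).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "percent", "n_meth", "n_unmeth"],
        dtype={"chrom": str},
    )
    pos = df["start"].astype(int) - (1 if one_based else 0)
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": pos,
            "n_meth": df["n_meth"].astype(int),
            "n_unmeth": df["n_unmeth"].astype(int),
        }
    )


def merge_strands(
    plus_calls: pd.DataFrame,
    minus_calls: pd.DataFrame,
    depth_min: int = DEPTH_MIN,
    cpg_positions: set[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Pool plus- and minus-strand calls per CpG unit.

    ``plus_calls``/``minus_calls`` carry (chrom, pos, n_meth, n_unmeth)
    with ``pos`` the called cytosine's coordinate on its strand mapped to
    the plus strand; a minus-strand call at p is assigned to the CpG unit
    at p - 1.  Counts are summed and the ratio recomputed from pooled
    counts.  When ``cpg_positions`` (reference plus-strand C coordinates)
    is given, units observed only on the minus strand with no reference
    partner are flagged ``orphan`` but kept.
    """
    plus = plus_calls.copy()
    plus["unit"] = plus["pos"]
    minus = minus_calls.copy()
    minus["unit"] = minus["pos"] - 1
    both = pd.concat([plus, minus], ignore_index=True)
    if both.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "n_meth", "n_unmeth", "depth", "ratio", "passes_depth", "orphan"]
        )
    merged = (
        both.groupby(["chrom", "unit"], as_index=False)[["n_meth", "n_unmeth"]]
        .sum()
        .rename(columns={"unit": "pos"})
    )
    merged["depth"] = merged["n_meth"] + merged["n_unmeth"]
    merged = merged[merged["depth"] > 0].reset_index(drop=True)
    merged["ratio"] = merged["n_meth"] / merged["depth"]
    merged["passes_depth"] = merged["depth"] >= depth_min
    if cpg_positions is not None:
        plus_units = set(zip(plus["chrom"], plus["unit"]))
        merged["orphan"] = [
            (c, p) not in cpg_positions and (c, p) not in plus_units
            for c, p in zip(merged["chrom"], merged["pos"])
        ]
        n_orphan = int(merged["orphan"].sum())
        if n_orphan:
            logger.warning("merge_strands: %d minus-strand calls without a reference CpG partner", n_orphan)
    else:
        merged["orphan"] = False
    return merged.sort_values(["chrom", "pos"]).reset_index(drop=True)


def conversion_efficiency(fill_in_calls: pd.DataFrame) -> float:
    """C-to-T conversion rate at MspI end-repair fill-in cytosines.

    These positions are filled in with unmethylated C during library
    preparation, so any C read there reflects incomplete conversion.
    Returns NaN when there are no observations.
    """
    n_c = int(fill_in_calls["n_meth"].sum())
    n_t = int(fill_in_calls["n_unmeth"].sum())
    if n_c + n_t == 0:
        return float("nan")
    return n_t / (n_c + n_t)


def correct_for_conversion(ratio, efficiency: float):
    """Remove the incomplete-conversion lift from observed methylation.

    An unmethylated C escapes conversion with probability 1 - efficiency
    and then reads as methylated, so observed = level + (1 - level) *
    (1 - efficiency); inverting gives the underlying level, clipped to
    [0, 1].
    """
    if not (0 < efficiency <= 1):
        raise ValueError("conversion efficiency must be in (0, 1]")
    return np.clip((np.asarray(ratio, dtype=float) - (1.0 - efficiency)) / efficiency, 0.0, 1.0)


def region_methylation(
    sites: pd.DataFrame, regions: pd.DataFrame, depth_min: int | None = None
) -> pd.DataFrame:
    """Unweighted mean of site methylation ratios per region.

    Only depth-passing sites contribute; a region with no passing site
    gets NaN.  ``regions`` needs (chrom, start, end, name); overlapping
    duplicate regions are reported independently.
    """
    use = sites
    if depth_min is not None:
        use = sites[(sites["n_meth"] + sites["n_unmeth"]) >= depth_min]
    elif "passes_depth" in sites.columns:
        use = sites[sites["passes_depth"]]
    by_chrom = {
        chrom: grp.sort_values("pos").reset_index(drop=True)
        for chrom, grp in use.groupby("chrom")
    }
    means, counts = [], []
    for row in regions.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            means.append(np.nan)
            counts.append(0)
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="left")
        n = hi - lo
        counts.append(int(n))
        means.append(float(grp["ratio"].iloc[lo:hi].mean()) if n else np.nan)
    out = regions.copy()
    out["mean_methylation"] = means
    out["n_sites"] = counts
    return out


def cgi_partition_summary(sites: pd.DataFrame, cgi: pd.DataFrame) -> pd.DataFrame:
    """Global mean methylation of depth-passing CpGs inside vs outside CGIs."""
    use = sites[sites["passes_depth"]] if "passes_depth" in sites.columns else sites
    in_cgi = np.zeros(len(use), dtype=bool)
    for chrom, grp in cgi.groupby("chrom"):
        mask = use["chrom"] == chrom
        pos = use.loc[mask, "pos"].to_numpy()
        hit = np.zeros(len(pos), dtype=bool)
        for row in grp.itertuples(index=False):
            hit |= (pos >= row.start) & (pos < row.end)
        in_cgi[np.flatnonzero(mask.to_numpy())] = hit
    rows = []
    for label, mask in (("CGI", in_cgi), ("non-CGI", ~in_cgi)):
        sub = use.loc[mask, "ratio"]
        rows.append((label, float(sub.mean()) if len(sub) else np.nan, int(len(sub))))
    return pd.DataFrame(rows, columns=["partition", "mean_methylation", "n_sites"])
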