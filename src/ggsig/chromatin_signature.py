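"""TSS-centred coverage extraction and chromatin-mark enrichment ranking.

Per-base normalised coverage (RPM) is read from bedGraph tracks over a
symmetric window around each promoter TSS, with minus-strand rows reversed
so that columns align in transcription orientation.  A dataset's
enrichment in a target promoter set versus a background set is

    log2FC = log2((mean_target + c) / (mean_background + c)),

where each set mean is the mean over promoters of the per-promoter mean
coverage and c is a small pseudocount (0.01 RPM) keeping zero-coverage
tracks finite.  Datasets are ranked by descending log2FC.  The background
is either all HCPs or the transcriptionally inactive HCPs (gene FPKM < 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .promoter_model import PromoterRecord

logger = logging.getLogger(__name__)

PSEUDOCOUNT_RPM = 0.01
DEFAULT_FLANK_BP = 250


@dataclass
class SignalProfile:
    """Promoters x positions matrix of per-base coverage for one dataset."""

    dataset_id: str
    promoter_ids: list[str]
    matrix: np.ndarray  # shape (n_promoters, 2*flank_bp)
    flank_bp: int
    flagged: list[str] = field(default_factory=list)

    def row(self, promoter_id: str) -> np.ndarray:
        return self.matrix[self.promoter_ids.index(promoter_id)]


@dataclass(frozen=True)
class EnrichmentScore:
    dataset_id: str
    log2fc: float
    target_mean: float
    background_mean: float
    background_kind: str


class BedGraphTrack:
    """Sparse per-chromosome coverage from a 4-column bedGraph (0-based half-open)."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = data

    @classmethod
    def read(cls, path: str) -> "BedGraphTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                try:
                    start, end, value = int(f[1]), int(f[2]), float(f[3])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from exc
                if end <= start:
                    raise ValueError(f"{path}:{lineno}: empty/negative interval")
                per_chrom.setdefault(f[0], []).append((start, end, value))
        data = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = np.array([i[0] for i in ivs], dtype=np.int64)
            ends = np.array([i[1] for i in ivs], dtype=np.int64)
            values = np.array([i[2] for i in ivs], dtype=np.float64)
            data[chrom] = (starts, ends, values)
        return cls(data)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are 0."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self._data:
            return out
        starts, ends, values = self._data[chrom]
        pos = np.arange(max(start, 0), end, dtype=np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        valid = (idx >= 0) & (ends[np.clip(idx, 0, None)] > pos)
        vals = np.where(valid, values[np.clip(idx, 0, None)], 0.0)
        out[(pos - start)] = vals
        return out

    def span(self, chrom: str) -> int:
        if chrom not in self._data:
            return 0
        return int(self._data[chrom][1][-1])


def tss_profile(
    track: BedGraphTrack | str,
    promoters: list[PromoterRecord],
    flank_bp: int = DEFAULT_FLANK_BP,
    dataset_id: str = "track",
) -> SignalProfile:
    """Per-base coverage over [tss - flank, tss + flank) for each promoter.

    Minus-strand rows are reversed so the matrix reads 5'->3' in
    transcription orientation; on both strands the TSS base is the first
    base of the downstream half (column ``flank_bp``), so minus-strand
    windows span ``[tss - flank + 1, tss + flank + 1)`` on the forward
    axis.  Bases falling before position 0 read as 0 and the promoter is
    flagged.
    """
    if isinstance(track, str):
        track = BedGraphTrack.read(track)
    width = 2 * flank_bp
    matrix = np.zeros((len(promoters), width))
    ids, flagged = [], []
    for i, p in enumerate(promoters):
        if p.strand == "+":
            lo, hi = p.tss - flank_bp, p.tss + flank_bp
        else:
            lo, hi = p.tss - flank_bp + 1, p.tss + flank_bp + 1
        row = track.values(p.chrom, lo, hi)
        if lo < 0:
            flagged.append(p.promoter_id)
        if p.strand == "-":
            row = row[::-1]
        matrix[i] = row
        ids.append(p.promoter_id)
    return SignalProfile(dataset_id, ids, matrix, flank_bp, flagged)


def _set_rows(profile: SignalProfile, ids, set_name: str) -> np.ndarray:
    ids = list(ids)
    if not ids:
        raise ValueError(f"promoter set {set_name!r} is empty")
    index = {pid: i for i, pid in enumerate(profile.promoter_ids)}
    missing = [pid for pid in ids if pid not in index]
    if missing:
        raise ValueError(f"promoter set {set_name!r} has ids absent from profile: {missing[:5]}")
    return profile.matrix[[index[pid] for pid in ids]]


def set_enrichment(
    profile: SignalProfile,
    target_ids,
    background_ids,
    pseudocount: float = PSEUDOCOUNT_RPM,
    background_kind: str = "all_HCP",
) -> EnrichmentScore:
    """log2 fold change of target-set over background-set mean coverage."""
    t = float(_set_rows(profile, target_ids, "target").mean(axis=1).mean())
    b = float(_set_rows(profile, background_ids, "background").mean(axis=1).mean())
    log2fc = float(np.log2((t + pseudocount) / (b + pseudocount)))
    return EnrichmentScore(profile.dataset_id, log2fc, t, b, background_kind)


def inactive_set(
    expression: pd.DataFrame,
    promoters: list[PromoterRecord],
    fpkm_max: float = 1.0,
    gene_col: str = "gene_id",
    fpkm_col: str = "fpkm",
) -> set[str]:
    """HCP promoters of transcriptionally inactive genes (FPKM strictly < 1)."""
    fpkm = dict(zip(expression[gene_col], expression[fpkm_col]))
    out: set[str] = set()
    missing = []
    for p in promoters:
        if p.cls != "HCP":
            continue
        if p.gene_id not in fpkm:
            missing.append(p.gene_id)
            continue
        if fpkm[p.gene_id] < fpkm_max:
            out.add(p.promoter_id)
    if missing:
        logger.warning(
            "inactive_set: %d HCP genes missing from expression table (excluded)",
            len(missing),
        )
    if not out:
        logger.warning("inactive_set: no inactive HCP promoters found")
    return out


def rank_datasets(scores: list[EnrichmentScore]) -> pd.DataFrame:
    """Rank datasets by descending log2FC; ties broken by dataset id."""
    if not scores:
        raise ValueError("no enrichment scores to rank")
    df = pd.DataFrame(
        {
            "dataset_id": [s.dataset_id for s in scores],
            "background_kind": [s.background_kind for s in scores],
            "target_mean": [s.target_mean for s in scores],
            "background_mean": [s.background_mean for s in scores],
            "log2fc": [s.log2fc for s in scores],
        }
    )
    df = df.sort_values(
        ["log2fc", "dataset_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def heatmap_matrix(
    profiles: list[SignalProfile],
    target_ids,
    background_ids,
    bin_bp: int = 1,
    pseudocount: float = PSEUDOCOUNT_RPM,
) -> pd.DataFrame:
    """Dataset x position log2FC matrix for TSS-centred heatmaps.

    Positions are offsets from the TSS; with ``bin_bp > 1`` the target and
    background mean coverages are averaged within each bin before the
    ratio is taken.  ``bin_bp = 1`` is the unbinned per-base matrix.
    """
    rows = {}
    columns = None
    for profile in profiles:
        t = _set_rows(profile, target_ids, "target").mean(axis=0)
        b = _set_rows(profile, background_ids, "background").mean(axis=0)
        if bin_bp > 1:
            width = len(t) - len(t) % bin_bp
            t = t[:width].reshape(-1, bin_bp).mean(axis=1)
            b = b[:width].reshape(-1, bin_bp).mean(axis=1)
        fc = np.log2((t + pseudocount) / (b + pseudocount))
        offsets = np.arange(len(fc)) * bin_bp - profile.flank_bp
        if columns is None:
            columns = offsets
        rows[profile.dataset_id] = fc
    return pd.DataFrame(rows, index=columns).T
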