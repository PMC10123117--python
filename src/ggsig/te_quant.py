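"""Fractional counting of multi-mapping reads into transposable-element families.

Each read (or fragment, for paired-end data) distributes one unit of
weight over its reported alignments: every alignment receives 1/k where
k is the read's number of mapping sites (the NH tag when consistent with
the records present, otherwise the record count).  An alignment
overlapping annotation intervals of exactly one family adds its weight
to that family once, however many intervals it touches; an alignment
overlapping several distinct families splits its weight equally among
them, so total assigned weight never exceeds the number of aligned
reads.  Family counts feed the shared negative-binomial two-group test
after rounding to integers.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .ipms_stats import nb_test

logger = logging.getLogger(__name__)


class TEAnnotation:
    """Repeat intervals indexed per chromosome, each carrying a family id."""

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "start", "end", "family_id"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"TE annotation missing columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for row in self.table.itertuples(index=False):
            self._trees.setdefault(row.chrom, IntervalTree()).addi(
                int(row.start), int(row.end), row.family_id
            )

    @classmethod
    def read(cls, path: str) -> "TEAnnotation":
        """Read a RepeatMasker-style TSV (header with chrom/start/end/family_id)
        or a BED6 whose name field is ``element:family``."""
        with open(path) as fh:
            first = fh.readline()
        if "family_id" in first:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        else:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                names=["chrom", "start", "end", "name", "score", "strand"],
                dtype={"chrom": str},
            )
            parts = df["name"].str.split(":", n=1)
            df["element_name"] = parts.str[0]
            df["family_id"] = parts.str[-1]
        return cls(df)

    def families_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    @property
    def families(self) -> list[str]:
        return sorted(set(self.table["family_id"]))


def read_weight(alignments: list) -> list[float]:
    """1/k weight per alignment of one read, k = number of mapping sites.

    The NH tag is used when present and consistent with the number of
    records; on disagreement the record count wins and a warning is
    emitted.
    """
    if not alignments:
        raise ValueError("read has no alignments")
    k = len(alignments)
    nh_values = {
        aln.get_tag("NH") for aln in alignments if aln.has_tag("NH")
    }
    if nh_values:
        if len(nh_values) == 1 and nh_values == {k}:
            pass
        else:
            logger.warning(
                "read %s: NH tag %s inconsistent with %d records; using record count",
                alignments[0].query_name,
                sorted(nh_values),
                k,
            )
    return [1.0 / k] * k


def _fragment_records(alignments: list) -> list:
    """Collapse mate pairs to one record per fragment (read1 preferred)."""
    if any(aln.is_paired for aln in alignments):
        primary = [aln for aln in alignments if not aln.is_read2]
        if primary:
            return primary
    return alignments


def te_family_counts(
    sam_path: str, annotation: TEAnnotation, min_overlap_bp: int = 1
) -> tuple[pd.Series, int]:
    """Fractional per-family counts from one SAM file.

    Returns (counts indexed by family, number of distinct aligned reads).
    Unmapped records are skipped; an alignment must overlap a repeat
    interval by at least ``min_overlap_bp`` bases to count.
    """
    by_read: dict[str, list] = defaultdict(list)
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if aln.reference_start is None or aln.reference_end is None:
                raise ValueError(f"malformed alignment record {aln.query_name!r}")
            by_read[aln.query_name].append(aln)

    counts: dict[str, float] = defaultdict(float)
    for _, alignments in sorted(by_read.items()):
        records = _fragment_records(alignments)
        weights = read_weight(records)
        for aln, w in zip(records, weights):
            start, end = aln.reference_start, aln.reference_end
            fams = {
                fam
                for fam in annotation.families_overlapping(
                    aln.reference_name, start, end
                )
                if _overlap_len(annotation, aln.reference_name, start, end, fam)
                >= min_overlap_bp
            }
            if not fams:
                continue
            share = w / len(fams)
            for fam in sorted(fams):
                counts[fam] += share
    series = pd.Series(
        {fam: counts.get(fam, 0.0) for fam in annotation.families}, name="count"
    )
    return series, len(by_read)


def _overlap_len(
    annotation: TEAnnotation, chrom: str, start: int, end: int, family: str
) -> int:
    tree = annotation._trees.get(chrom)
    best = 0
    if tree is None:
        return 0
    for iv in tree.overlap(start, end):
        if iv.data != family:
            continue
        best = max(best, min(end, iv.end) - max(start, iv.begin))
    return best


def count_samples(
    sam_paths: dict[str, str], annotation: TEAnnotation, min_overlap_bp: int = 1
) -> pd.DataFrame:
    """Family x sample fractional count matrix from several SAM files."""
    cols = {}
    for sample, path in sam_paths.items():
        series, _ = te_family_counts(path, annotation, min_overlap_bp)
        cols[sample] = series
    return pd.DataFrame(cols)


def te_differential(
    counts: pd.DataFrame, group_labels, numerator: str, denominator: str
) -> pd.DataFrame:
    """Two-group NB test on family counts (rounded half-to-even to integers).

    Families with no counts in any sample are excluded by the test.
    """
    rounded = pd.DataFrame(
        np.rint(counts.to_numpy(dtype=float)).astype(int),
        index=counts.index,
        columns=counts.columns,
    )
    stats = nb_test(rounded, group_labels, numerator, denominator)
    return stats.rename(columns={"protein": "family_id"})
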