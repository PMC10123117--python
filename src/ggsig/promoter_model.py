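"""Promoter CpG-density classification (LCP / ICP / HCP).

Promoters are defined as the interval from 1000 bp upstream to 500 bp
downstream of the TSS in transcription orientation.  Each promoter is
scanned with 500-bp windows advancing in 20-bp steps; for every window we
record the GC content and the observed/expected CpG ratio

    cpg_ratio = (n_CpG * L) / (n_C * n_G),

where ``L`` is the window length.  A promoter is HCP when at least one
window has ``cpg_ratio > 0.65`` and ``gc_content > 0.55``; LCP when no
window has ``cpg_ratio > 0.45``; ICP otherwise.  The HCP rule is tested
first, so the three classes partition all classified promoters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

WINDOW_BP = 500
STEP_BP = 20
UPSTREAM_BP = 1000
DOWNSTREAM_BP = 500
PROMOTER_BP = UPSTREAM_BP + DOWNSTREAM_BP

HCP_CPG_RATIO = 0.65
HCP_GC = 0.55
LCP_CPG_RATIO = 0.45
MAX_N_FRACTION = 0.10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class WindowStat:
    """CpG ratio and GC content of one 500-bp window."""

    offset_bp: int
    cpg_ratio: float
    gc_content: float


@dataclass
class PromoterRecord:
    """One promoter: interval, class and CpG metrics.

    ``start``/``end`` are 0-based half-open forward-axis coordinates; the
    window statistics and ``n_cpg`` refer to the transcription-orientation
    sequence (reverse-complemented for minus-strand promoters).
    """

    gene_id: str
    transcript_ids: list[str]
    chrom: str
    tss: int
    strand: str
    start: int
    end: int
    cls: str  # LCP / ICP / HCP / NA
    n_cpg: int
    cgi_size_bp: int
    max_cpg_ratio: float
    max_gc: float
    truncated: bool = False

    @property
    def promoter_id(self) -> str:
        return f"{self.chrom}:{self.tss}:{self.strand}"


def window_stats(
    sequence: str, window_bp: int = WINDOW_BP, step_bp: int = STEP_BP
) -> list[WindowStat]:
    """Sliding-window CpG ratio and GC content over *sequence*.

    Only fully contained windows are scored.  Windows with more than 10%
    N are skipped; the GC denominator excludes N bases.  The CpG ratio is
    0 when the window contains no C or no G.
    """
    seq = sequence.upper()
    if set(seq) - _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    n = len(seq)
    if n < window_bp:
        return []

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (arr == ord("N")).astype(np.int64)
    # CpG dinucleotide starting at i
    is_cpg = np.zeros(n, dtype=np.int64)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])

    out: list[WindowStat] = []
    for off in range(0, n - window_bp + 1, step_bp):
        hi = off + window_bp
        n_n = int(cum_n[hi] - cum_n[off])
        if n_n > MAX_N_FRACTION * window_bp:
            continue
        n_c = int(cum_c[hi] - cum_c[off])
        n_g = int(cum_g[hi] - cum_g[off])
        # CpG starting positions within [off, hi-1]: dinucleotide must fit
        n_cpg = int(cum_cpg[hi - 1] - cum_cpg[off])
        denom = n_c * n_g
        ratio = (n_cpg * window_bp) / denom if denom > 0 else 0.0
        non_n = window_bp - n_n
        gc = (n_c + n_g) / non_n if non_n > 0 else 0.0
        out.append(WindowStat(offset_bp=off, cpg_ratio=ratio, gc_content=gc))
    return out


def classify_promoter(windows: list[WindowStat]) -> str:
    """LCP/ICP/HCP call from window statistics; NA for an empty list."""
    if not windows:
        return "NA"
    if any(w.cpg_ratio > HCP_CPG_RATIO and w.gc_content > HCP_GC for w in windows):
        return "HCP"
    if all(w.cpg_ratio <= LCP_CPG_RATIO for w in windows):
        return "LCP"
    return "ICP"


def classify_sequence(sequence: str) -> str:
    return classify_promoter(window_stats(sequence))


def count_cpg(sequence: str) -> int:
    seq = sequence.upper()
    return sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")


# ---------------------------------------------------------------------------
# annotation readers


def read_tss_bed(path: str) -> pd.DataFrame:
    """Read a BED6 TSS annotation into (gene_id, transcript_id, chrom, tss, strand).

    The name field is ``gene_id|transcript_id``; a bare name is used for
    both.  The TSS is the start for plus-strand and ``end - 1`` for
    minus-strand entries (identical for 1-bp features).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    recs = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"missing/invalid strand for TSS record {row.name!r}")
        gene, _, tx = row.name.partition("|")
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        recs.append((gene, tx or row.name, row.chrom, tss, row.strand))
    return pd.DataFrame(
        recs, columns=["gene_id", "transcript_id", "chrom", "tss", "strand"]
    )


def read_tss_gtf(path: str) -> pd.DataFrame:
    """Extract per-transcript TSS from GTF transcript features (1-based input)."""
    import re

    recs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gid = re.search(r'gene_id "([^"]+)"', attrs)
            tid = re.search(r'transcript_id "([^"]+)"', attrs)
            gene = gid.group(1) if gid else "NA"
            tx = tid.group(1) if tid else gene
            tss = start - 1 if strand == "+" else end - 1
            recs.append((gene, tx, chrom, tss, strand))
    return pd.DataFrame(
        recs, columns=["gene_id", "transcript_id", "chrom", "tss", "strand"]
    )


def read_tss_table(path: str) -> pd.DataFrame:
    if path.endswith((".gtf", ".gff")):
        return read_tss_gtf(path)
    return read_tss_bed(path)


def read_cgi_bed(path: str) -> dict[str, IntervalTree]:
    """CGI BED3 into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    for row in df.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(int(row.start), int(row.end))
    return trees


# ---------------------------------------------------------------------------
# promoter construction


def promoter_interval(tss: int, strand: str) -> tuple[int, int]:
    """Forward-axis half-open interval of the -1000..+500 promoter."""
    if strand == "+":
        return tss - UPSTREAM_BP, tss + DOWNSTREAM_BP
    return tss - DOWNSTREAM_BP + 1, tss + UPSTREAM_BP + 1


def build_promoters(
    annotation: pd.DataFrame,
    genome: Fasta | str,
    cgi: dict[str, IntervalTree] | None = None,
) -> list[PromoterRecord]:
    """Build classified promoter records from a TSS table and a genome.

    Duplicate ``(chrom, tss, strand)`` promoters are collapsed into one
    record listing all transcript ids.  Promoters extending past a contig
    edge are truncated and flagged; windows are computed on the remaining
    sequence (class NA when shorter than one window).  An unknown
    chromosome raises, naming the offending record.
    """
    if isinstance(genome, str):
        genome = Fasta(genome)
    cgi = cgi or {}

    grouped: dict[tuple[str, int, str], dict] = {}
    for row in annotation.itertuples(index=False):
        key = (row.chrom, int(row.tss), row.strand)
        entry = grouped.setdefault(key, {"genes": [], "txs": []})
        entry["genes"].append(row.gene_id)
        entry["txs"].append(row.transcript_id)

    records: list[PromoterRecord] = []
    for (chrom, tss, strand), entry in sorted(grouped.items()):
        if chrom not in genome:
            raise ValueError(
                f"unknown chromosome {chrom!r} for promoter of "
                f"{entry['genes'][0]!r} (tss={tss})"
            )
        chrom_len = len(genome[chrom])
        if not (0 <= tss < chrom_len):
            raise ValueError(
                f"TSS {tss} outside chromosome {chrom!r} (length {chrom_len}) "
                f"for {entry['genes'][0]!r}"
            )
        start, end = promoter_interval(tss, strand)
        truncated = start < 0 or end > chrom_len
        cstart, cend = max(start, 0), min(end, chrom_len)
        seq = str(genome[chrom][cstart:cend]).upper()
        if strand == "-":
            seq = reverse_complement(seq)
        windows = window_stats(seq)
        cls = classify_promoter(windows)
        cgi_size = 0
        if chrom in cgi:
            hits = cgi[chrom].overlap(cstart, cend)
            if hits:
                cgi_size = max(iv.end - iv.begin for iv in hits)
        records.append(
            PromoterRecord(
                gene_id=entry["genes"][0],
                transcript_ids=sorted(set(entry["txs"])),
                chrom=chrom,
                tss=tss,
                strand=strand,
                start=cstart,
                end=cend,
                cls=cls,
                n_cpg=count_cpg(seq),
                cgi_size_bp=cgi_size,
                max_cpg_ratio=max((w.cpg_ratio for w in windows), default=0.0),
                max_gc=max((w.gc_content for w in windows), default=0.0),
                truncated=truncated,
            )
        )
    return records


_CLASS_ORDER = {"HCP": 3, "ICP": 2, "LCP": 1, "NA": 0}


def gene_classes(records: list[PromoterRecord]) -> dict[str, str]:
    """Gene-level class = strongest CpG class over the gene's promoters."""
    best: dict[str, str] = {}
    for r in records:
        cur = best.get(r.gene_id, "NA")
        if _CLASS_ORDER[r.cls] > _CLASS_ORDER[cur]:
            best[r.gene_id] = r.cls
        else:
            best.setdefault(r.gene_id, cur)
    return best


def promoters_to_frame(records: list[PromoterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "transcript_ids": [",".join(r.transcript_ids) for r in records],
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "strand": [r.strand for r in records],
            "tss": [r.tss for r in records],
            "class": [r.cls for r in records],
            "n_cpg": [r.n_cpg for r in records],
            "cgi_size_bp": [r.cgi_size_bp for r in records],
            "max_cpg_ratio": [r.max_cpg_ratio for r in records],
            "max_gc": [r.max_gc for r in records],
            "truncated": [r.truncated for r in records],
        }
    )


def write_promoter_table(records: list[PromoterRecord], path: str) -> None:
    promoters_to_frame(records).to_csv(path, sep="\t", index=False)


def read_promoter_table(path: str) -> list[PromoterRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.rename(columns={"class": "cls"})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PromoterRecord(
                gene_id=row.gene_id,
                transcript_ids=str(row.transcript_ids).split(","),
                chrom=row.chrom,
                tss=int(row.tss),
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                cls=row.cls,
                n_cpg=int(row.n_cpg),
                cgi_size_bp=int(row.cgi_size_bp),
                max_cpg_ratio=float(row.max_cpg_ratio),
                max_gc=float(row.max_gc),
                truncated=bool(row.truncated),
            )
        )
    return out
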