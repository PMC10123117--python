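"""Promoter window statistics and LCP/ICP/HCP classification."""

import numpy as np
import pandas as pd
import pytest

from ggsig import promoter_model as pm
from ggsig.promoter_model import (
    PromoterRecord,
    WindowStat,
    build_promoters,
    classify_promoter,
    classify_sequence,
    count_cpg,
    gene_classes,
    promoter_interval,
    reverse_complement,
    window_stats,
)


def naive_window_stats(seq: str, window=500, step=20):
    """Brute-force recount oracle: direct substring counting per window."""
    seq = seq.upper()
    out = []
    for off in range(0, len(seq) - window + 1, step):
        w = seq[off : off + window]
        n_n = w.count("N")
        if n_n > 0.10 * window:
            continue
        n_c, n_g = w.count("C"), w.count("G")
        n_cpg = sum(1 for i in range(window - 1) if w[i : i + 2] == "CG")
        ratio = n_cpg * window / (n_c * n_g) if n_c * n_g else 0.0
        gc = (n_c + n_g) / (window - n_n) if window > n_n else 0.0
        out.append((off, ratio, gc))
    return out


def random_seq(rng, n, p=(0.3, 0.2, 0.2, 0.3)):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestWindowStats:
    def test_tandem_cg_window(self):
        (w,) = window_stats("CG" * 250)
        assert w.cpg_ratio == 2.0 and w.gc_content == 1.0

    def test_all_a_window(self):
        (w,) = window_stats("A" * 500)
        assert w.cpg_ratio == 0.0 and w.gc_content == 0.0

    def test_short_sequence_empty(self):
        assert window_stats("ACGT" * 100) == []

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            window_stats("ACGTX" * 100)

    def test_520bp_two_windows_match_naive(self, rng):
        seq = random_seq(rng, 520)
        got = window_stats(seq)
        expected = naive_window_stats(seq)
        assert [w.offset_bp for w in got] == [0, 20]
        for w, (off, ratio, gc) in zip(got, expected):
            assert w.offset_bp == off
            assert w.cpg_ratio == pytest.approx(ratio, abs=0)
            assert w.gc_content == pytest.approx(gc, abs=0)

    def test_oracle_equivalence_random_promoters(self, rng):
        for _ in range(100):
            seq = random_seq(rng, 1500)
            got = [(w.offset_bp, w.cpg_ratio, w.gc_content) for w in window_stats(seq)]
            assert got == naive_window_stats(seq)

    def test_n_rich_window_skipped_and_gc_excludes_n(self):
        # >10% N: skipped entirely
        assert window_stats("N" * 60 + "A" * 440) == []
        # 5% N: kept, GC denominator excludes the Ns
        (w,) = window_stats("N" * 25 + "G" * 475)
        assert w.gc_content == pytest.approx(475 / 475)


class TestClassifyPromoter:
    def mk(self, pairs):
        return [WindowStat(20 * i, r, g) for i, (r, g) in enumerate(pairs)]

    def test_all_low_ratio_is_lcp(self):
        assert classify_promoter(self.mk([(0.40, 0.5)] * 10)) == "LCP"

    def test_single_qualifying_window_is_hcp(self):
        ws = self.mk([(0.2, 0.4)] * 9 + [(0.70, 0.60)])
        assert classify_promoter(ws) == "HCP"

    def test_intermediate_is_icp(self):
        assert classify_promoter(self.mk([(0.50, 0.50)] * 10)) == "ICP"

    def test_hcp_needs_both_conditions_in_same_window(self):
        # ratio high in one window, GC high in another: not HCP
        ws = self.mk([(0.70, 0.50)] + [(0.2, 0.4)] * 9)
        assert classify_promoter(ws) == "ICP"
        ws = self.mk([(0.70, 0.50), (0.40, 0.60)] + [(0.2, 0.4)] * 8)
        assert classify_promoter(ws) == "ICP"

    def test_empty_is_na(self):
        assert classify_promoter([]) == "NA"

    def test_threshold_boundaries_strict(self):
        # exactly at the threshold does not qualify
        assert classify_promoter(self.mk([(0.65, 0.60)] * 3)) == "ICP"
        assert classify_promoter(self.mk([(0.70, 0.55)] * 3)) == "ICP"
        assert classify_promoter(self.mk([(0.45, 0.5)] * 3)) == "LCP"

    def test_monotone_in_cpg_ratio(self, rng):
        """Raising one window's CpG ratio never demotes the class."""
        order = {"LCP": 0, "ICP": 1, "HCP": 2}
        for _ in range(50):
            pairs = [(rng.uniform(0, 0.9), rng.uniform(0.3, 0.7)) for _ in range(8)]
            before = classify_promoter(self.mk(pairs))
            i = rng.integers(0, 8)
            raised = list(pairs)
            raised[i] = (pairs[i][0] + rng.uniform(0, 0.5), pairs[i][1])
            after = classify_promoter(self.mk(raised))
            assert order[after] >= order[before]

    def test_strand_symmetry(self, rng):
        for _ in range(25):
            seq = random_seq(rng, 1500)
            assert classify_sequence(seq) == classify_sequence(reverse_complement(seq))


class TestBuildPromoters:
    @pytest.fixture()
    def genome_fa(self, tmp_path, rng):
        seq = random_seq(rng, 20000)
        path = tmp_path / "g.fa"
        path.write_text(">chr1\n" + "\n".join(seq[i : i + 80] for i in range(0, 20000, 80)) + "\n")
        return str(path), seq

    def ann(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "transcript_id", "chrom", "tss", "strand"]
        )

    def test_plus_strand_interval(self, genome_fa):
        path, _ = genome_fa
        (r,) = build_promoters(self.ann([("g1", "t1", "chr1", 10000, "+")]), path)
        assert (r.start, r.end) == (9000, 10500)
        assert not r.truncated

    def test_minus_strand_interval_and_revcomp(self, genome_fa):
        path, seq = genome_fa
        (r,) = build_promoters(self.ann([("g1", "t1", "chr1", 10000, "-")]), path)
        assert (r.start, r.end) == (9501, 11001)
        rc = reverse_complement(seq[9501:11001])
        assert r.n_cpg == count_cpg(rc)
        assert r.cls == classify_sequence(rc)

    def test_duplicate_tss_deduplicated(self, genome_fa):
        path, _ = genome_fa
        rows = [("g1", "t1", "chr1", 10000, "+"), ("g1", "t2", "chr1", 10000, "+")]
        (r,) = build_promoters(self.ann(rows), path)
        assert r.transcript_ids == ["t1", "t2"]

    def test_unknown_chromosome_rejected(self, genome_fa):
        path, _ = genome_fa
        with pytest.raises(ValueError, match="chrX.*g1"):
            build_promoters(self.ann([("g1", "t1", "chrX", 10000, "+")]), path)

    def test_edge_tss_flagged_truncated(self, genome_fa):
        path, _ = genome_fa
        (r,) = build_promoters(self.ann([("g1", "t1", "chr1", 600, "+")]), path)
        assert r.truncated and r.start == 0

    def test_no_cgi_size_zero_and_largest_overlap(self, genome_fa):
        path, _ = genome_fa
        from intervaltree import IntervalTree

        trees = {"chr1": IntervalTree()}
        trees["chr1"].addi(9500, 9800)
        trees["chr1"].addi(10000, 10900)
        rows = [("g1", "t1", "chr1", 10000, "+"), ("g2", "t2", "chr1", 15000, "+")]
        r1, r2 = build_promoters(self.ann(rows), path, trees)
        assert r1.cgi_size_bp == 900  # largest overlapping CGI
        assert r2.cgi_size_bp == 0

    def test_gene_class_aggregation_takes_strongest(self):
        recs = [
            PromoterRecord("g", ["a"], "chr1", 0, "+", 0, 1, cls, 0, 0, 0.0, 0.0)
            for cls in ("LCP", "HCP", "ICP")
        ]
        assert gene_classes(recs) == {"g": "HCP"}

    def test_promoter_interval_minus_mirror(self):
        # minus-strand -1000..+500 spans tss-500..tss+1000 on the forward axis
        assert promoter_interval(10000, "-") == (9501, 11001)
        assert promoter_interval(10000, "+") == (9000, 10500)


def test_promoter_table_roundtrip(tmp_path, sim_dir):
    ann = pm.read_tss_table(str(sim_dir / "genome/tss.bed"))
    cgi = pm.read_cgi_bed(str(sim_dir / "genome/cgi.bed"))
    records = build_promoters(ann, str(sim_dir / "genome/genome.fa"), cgi)
    out = tmp_path / "prom.tsv"
    pm.write_promoter_table(records, str(out))
    back = pm.read_promoter_table(str(out))
    assert len(back) == len(records)
    assert [r.cls for r in back] == [r.cls for r in records]
    assert [r.promoter_id for r in back] == [r.promoter_id for r in records]
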