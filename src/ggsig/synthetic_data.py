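"""Seeded generators for every input the pipeline consumes, with planted truth.

Each generator is a pure function of a :class:`SimConfig`: the same seed
yields byte-identical files.  The generators emulate the statistical
structure of the real inputs — promoter sequences drawn from
CpG-depleted or CpG-rich compositions, RPM coverage tracks with planted
fold changes at a target promoter set, negative-binomial gRNA / RNA /
spectral counts with planted effects, binomial bisulfite calls with
conversion error, and multi-mapping repeat alignments — without any
claim to realistic mammalian genome composition.

Planted promoter classes are verified against the package's own
classifier before emission (resampling on failure), so classifier tests
are self-consistent rather than distribution-dependent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import promoter_model
from .promoter_model import classify_sequence, reverse_complement

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    seed: int = 1

    # genome / promoters
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_promoters: int = 300
    class_fractions: dict = field(
        default_factory=lambda: {"HCP": 0.6, "ICP": 0.2, "LCP": 0.2}
    )
    n_targets: int = 40  # planted germline-like inactive HCPs
    inactive_fraction: float = 0.35  # non-target HCP genes with FPKM < 1

    # chromatin tracks
    marks: dict = field(
        default_factory=lambda: {
            f"mark{i:02d}_fc{fc:+d}": float(fc)
            for i, fc in enumerate(
                [-2, -1, 0, 1, 2] * 4
            )
        }
    )
    track_base_rpm: float = 1.0
    track_noise_sigma: float = 0.1
    track_bin_bp: int = 20
    track_flank_bp: int = 1200

    # CRISPR screen
    screen_n_genes: int = 2000
    grnas_per_gene: int = 4
    screen_n_replicates: int = 3
    screen_mean: float = 200.0
    screen_dispersion: float = 0.05
    screen_n_hits: int = 15
    screen_enrichment: float = 6.0
    screen_n_olfactory: int = 50
    screen_n_olfactory_enriched: int = 5
    screen_n_lowexpr_enriched: int = 3

    # RNA
    rna_n_genes: int = 1000
    rna_n_up: int = 50
    rna_fold: float = 4.0
    rna_dispersion: float = 0.05
    rna_mean_log: float = 4.0
    rna_n_per_group: int = 3

    # bisulfite
    bis_region_levels: tuple = (0.05, 0.5, 0.95)
    bis_regions_per_level: int = 20
    bis_cpgs_per_region: int = 50
    bis_depth: float = 20.0
    bis_conversion: float = 0.99
    bis_n_fill_in: int = 1000

    # TE
    te_families: tuple = (
        "IAPEz", "IAPLTR1_Mm", "IAPEY", "MERVL", "MT2_Mm", "ETnERV", "MusD",
        "RLTR10", "RLTR45", "L1Md_T", "L1Md_A", "L1Md_F2", "Lx2", "L1_Mur2",
        "B1_Mus1", "B2_Mm1a", "B2_Mm2", "MTA_Mm", "ORR1A0", "MER46C",
    )
    te_copies_per_family: int = 8
    te_copy_length: int = 500
    te_reads_per_family: float = 300.0
    te_dispersion: float = 0.01
    te_planted_family: str = "IAPEz"
    te_fold: float = 4.0
    te_n_per_group: int = 3
    te_multimap_probs: dict = field(
        default_factory=lambda: {1: 0.5, 2: 0.25, 3: 0.15, 4: 0.10}
    )

    # IP-MS
    ipms_n_proteins: int = 400
    ipms_n_partners: int = 12
    ipms_background_mean: float = 20.0
    ipms_enrichment: float = 8.0
    ipms_partner_ko_mean: float = 5.0
    ipms_dispersion: float = 0.1
    ipms_n_per_group: int = 3

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _break_cpgs(arr: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Replace the G of CpG dinucleotides by T with probability *prob*."""
    is_cpg = (arr[:-1] == "C") & (arr[1:] == "G")
    idx = np.flatnonzero(is_cpg)
    hit = idx[rng.random(len(idx)) < prob]
    arr = arr.copy()
    arr[hit + 1] = "T"
    return arr


_CLASS_PARAMS = {
    # (P(C)=P(G), CpG-break probability)
    "HCP": (0.30, 0.0),
    "ICP": (0.25, 0.45),
    "LCP": (0.21, 0.85),
}


def _random_seq(n: int, p_cg: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([0.5 - p_cg, p_cg, p_cg, 0.5 - p_cg])
    return rng.choice(BASES, size=n, p=p)


def _promoter_sequence(cls: str, rng: np.random.Generator, max_tries: int = 50) -> str:
    p_cg, brk = _CLASS_PARAMS[cls]
    for _ in range(max_tries):
        arr = _random_seq(promoter_model.PROMOTER_BP, p_cg, rng)
        if brk:
            arr = _break_cpgs(arr, brk, rng)
        seq = "".join(arr)
        if classify_sequence(seq) == cls:
            return seq
    raise RuntimeError(f"could not generate a {cls} promoter in {max_tries} tries")


def sim_genome(cfg: SimConfig, outdir: str | Path) -> pd.DataFrame:
    """Genome FASTA + TSS BED + CGI BED + WT FPKM table + truth table.

    Promoters are evenly spaced with jitter; planted classes follow
    ``class_fractions``; the first ``n_targets`` HCP promoters are the
    germline-like target set (inactive, short CGIs).  Returns the truth
    table, also written as ``truth_promoters.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(1)

    classes = []
    for cls, frac in cfg.class_fractions.items():
        classes += [cls] * int(round(frac * cfg.n_promoters))
    classes = (classes + ["ICP"] * cfg.n_promoters)[: cfg.n_promoters]

    per_chrom = cfg.n_promoters // cfg.n_chromosomes
    spacing = (cfg.chrom_length - 6000) // per_chrom
    if spacing < 3500:
        raise ValueError("chromosomes too short for the requested promoter count")

    chrom_seqs = {}
    for c in range(cfg.n_chromosomes):
        arr = _random_seq(cfg.chrom_length, 0.21, rng)
        arr = _break_cpgs(arr, 0.85, rng)
        chrom_seqs[f"chr{c + 1}"] = arr

    rows = []
    hcp_seen = 0
    for i in range(cfg.n_promoters):
        chrom = f"chr{i // per_chrom + 1}"
        local = i % per_chrom
        tss = 3000 + local * spacing + int(rng.integers(0, min(2000, spacing - 3200)))
        strand = "+" if rng.random() < 0.5 else "-"
        cls = classes[i]
        seq = _promoter_sequence(cls, rng)
        start, end = promoter_model.promoter_interval(tss, strand)
        inserted = seq if strand == "+" else reverse_complement(seq)
        chrom_seqs[chrom][start:end] = np.array(list(inserted))

        is_target = False
        cgi_start = cgi_end = -1
        if cls == "HCP":
            hcp_seen += 1
            is_target = hcp_seen <= cfg.n_targets
            size = int(rng.integers(200, 600)) if is_target else int(rng.integers(400, 1500))
            cgi_start = tss - size // 2
            cgi_end = cgi_start + size
        if is_target:
            fpkm = float(rng.uniform(0.0, 0.9))
        elif cls == "HCP" and rng.random() < cfg.inactive_fraction:
            fpkm = float(rng.uniform(0.0, 0.9))
        else:
            fpkm = float(np.round(rng.lognormal(2.0, 1.0), 4))
        rows.append(
            {
                "gene_id": f"g{i:04d}",
                "chrom": chrom,
                "tss": tss,
                "strand": strand,
                "class": cls,
                "is_target": is_target,
                "fpkm": round(fpkm, 4),
                "cgi_start": cgi_start,
                "cgi_end": cgi_end,
            }
        )
    truth = pd.DataFrame(rows)

    with open(outdir / "genome.fa", "w") as fh:
        for chrom, arr in chrom_seqs.items():
            fh.write(f">{chrom}\n")
            s = "".join(arr)
            for j in range(0, len(s), 80):
                fh.write(s[j : j + 80] + "\n")

    with open(outdir / "tss.bed", "w") as fh:
        for r in rows:
            fh.write(
                f"{r['chrom']}\t{r['tss']}\t{r['tss'] + 1}\t"
                f"{r['gene_id']}|{r['gene_id']}.t1\t0\t{r['strand']}\n"
            )

    with open(outdir / "cgi.bed", "w") as fh:
        for r in rows:
            if r["cgi_start"] >= 0:
                fh.write(f"{r['chrom']}\t{r['cgi_start']}\t{r['cgi_end']}\n")

    truth[["gene_id", "fpkm"]].to_csv(outdir / "fpkm.tsv", sep="\t", index=False)
    with open(outdir / "targets.txt", "w") as fh:
        for g in truth.loc[truth["is_target"], "gene_id"]:
            fh.write(g + "\n")
    truth.to_csv(outdir / "truth_promoters.tsv", sep="\t", index=False)
    return truth


def sim_tracks(cfg: SimConfig, truth: pd.DataFrame, outdir: str | Path) -> pd.DataFrame:
    """Per-mark bedGraph tracks with planted log2 fold change at target promoters.

    Coverage is ``track_base_rpm`` x lognormal noise in ``track_bin_bp``
    bins over each promoter neighbourhood; bins within 250 bp of a target
    TSS are multiplied by 2**planted_log2fc.  Returns the mark truth
    table (mark_id, planted_log2fc), written as ``truth_marks.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(2)
    flank, binw = cfg.track_flank_bp, cfg.track_bin_bp

    rows = []
    for mark, planted in sorted(cfg.marks.items()):
        fold = 2.0 ** planted
        with open(outdir / f"{mark}.bedGraph", "w") as fh:
            for p in truth.itertuples(index=False):
                lo = p.tss - flank
                bins = np.arange(lo, p.tss + flank, binw)
                noise = rng.lognormal(0.0, cfg.track_noise_sigma, size=len(bins))
                values = cfg.track_base_rpm * noise
                if p.is_target:
                    near = (bins + binw > p.tss - 250) & (bins < p.tss + 250)
                    values[near] *= fold
                for b, v in zip(bins, values):
                    fh.write(f"{p.chrom}\t{b}\t{b + binw}\t{v:.5f}\n")
        rows.append({"mark_id": mark, "planted_log2fc": planted})
    marks = pd.DataFrame(rows)
    marks.to_csv(outdir / "truth_marks.tsv", sep="\t", index=False)
    return marks


# ---------------------------------------------------------------------------
# CRISPR screen


def _binom_enrich_pvalue(y: np.ndarray, x: np.ndarray, ny: float, nx: float) -> np.ndarray:
    """One-sided conditional binomial p for sorted count y vs input count x."""
    from scipy.stats import binom

    t = x + y
    p = ny / (nx + ny)
    return binom.sf(y - 1, t, p)


def score_gene_summary(
    grna_input: pd.DataFrame, grna_sorted: pd.DataFrame, analysis_id: str
) -> pd.DataFrame:
    """Rank-by-minimum-p gene scorer emulating a MAGeCK-style gene summary.

    Per gRNA, a one-sided conditional binomial test compares the sorted
    count against the input count given library sizes; each gene's score
    is the smallest p over its gRNAs, its p-value the Bonferroni-adjusted
    minimum, and ranks follow ascending score with ties broken by gene.
    """
    x = grna_input["count"].to_numpy(dtype=float)
    y = grna_sorted["count"].to_numpy(dtype=float)
    p = _binom_enrich_pvalue(y, x, y.sum(), x.sum())
    per_grna = pd.DataFrame({"gene": grna_input["gene"], "p": p})
    genes = per_grna.groupby("gene", sort=True).agg(
        pos_score=("p", "min"), n_grna=("p", "size")
    )
    genes["pos_pvalue"] = np.minimum(1.0, genes["pos_score"] * genes["n_grna"])
    genes = genes.sort_values(["pos_score", "gene"], kind="mergesort").reset_index()
    genes["pos_rank"] = np.arange(1, len(genes) + 1)
    out = genes[["gene", "pos_score", "pos_pvalue", "pos_rank"]].copy()
    out.attrs["analysis_id"] = analysis_id
    return out


def sim_screen(cfg: SimConfig, outdir: str | Path) -> pd.DataFrame:
    """gRNA count tables, gene summaries (full + pairwise) and screen truth.

    Planted hit genes have their gRNA counts multiplied by
    ``screen_enrichment`` in every sorted (GFP+) replicate.  Decoys
    exercise the filter chain: enriched olfactory genes (Olfr prefix)
    and enriched genes with FPKM < 5.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(3)

    n_genes, g_per = cfg.screen_n_genes, cfg.grnas_per_gene
    names = [f"G{i:04d}" for i in range(n_genes)]
    for j in range(cfg.screen_n_olfactory):
        names[n_genes - cfg.screen_n_olfactory + j] = f"Olfr{j + 1:03d}"

    hits = [names[i] for i in range(cfg.screen_n_hits)]
    olf_enriched = [
        names[n_genes - cfg.screen_n_olfactory + j]
        for j in range(cfg.screen_n_olfactory_enriched)
    ]
    lowexpr_enriched = [
        names[cfg.screen_n_hits + j] for j in range(cfg.screen_n_lowexpr_enriched)
    ]
    enriched = set(hits) | set(olf_enriched) | set(lowexpr_enriched)

    genes_col = np.repeat(names, g_per)
    grna_col = [f"{g}_sg{k + 1}" for g in names for k in range(g_per)]
    enriched_mask = np.isin(genes_col, list(enriched))

    disp = cfg.screen_dispersion
    r = 1.0 / disp
    tables = {}
    for rep in range(1, cfg.screen_n_replicates + 1):
        base = rng.gamma(r, cfg.screen_mean / r, size=len(genes_col))
        inp = rng.poisson(base)
        sorted_mean = base * np.where(enriched_mask, cfg.screen_enrichment, 1.0)
        srt = rng.poisson(sorted_mean)
        tables[rep] = (
            pd.DataFrame({"grna": grna_col, "gene": genes_col, "count": inp}),
            pd.DataFrame({"grna": grna_col, "gene": genes_col, "count": srt}),
        )
        tables[rep][0].to_csv(outdir / f"grna_input_rep{rep}.tsv", sep="\t", index=False)
        tables[rep][1].to_csv(outdir / f"grna_sorted_rep{rep}.tsv", sep="\t", index=False)

    def pooled(reps):
        inp = tables[reps[0]][0].copy()
        srt = tables[reps[0]][1].copy()
        for rep in reps[1:]:
            inp["count"] += tables[rep][0]["count"]
            srt["count"] += tables[rep][1]["count"]
        return inp, srt

    all_reps = list(tables)
    summary = score_gene_summary(*pooled(all_reps), analysis_id="full")
    summary.to_csv(outdir / "gene_summary_full.tsv", sep="\t", index=False)
    for a in range(len(all_reps)):
        for b in range(a + 1, len(all_reps)):
            pair = (all_reps[a], all_reps[b])
            s = score_gene_summary(*pooled(list(pair)), analysis_id=f"rep{pair[0]}{pair[1]}")
            s.to_csv(outdir / f"gene_summary_rep{pair[0]}{pair[1]}.tsv", sep="\t", index=False)

    fpkm = pd.DataFrame({"gene_id": names})
    base_fpkm = np.round(rng.lognormal(2.5, 1.0, size=n_genes), 3)
    base_fpkm = np.maximum(base_fpkm, 5.0)  # default: expressed
    low = rng.random(n_genes) < 0.2
    base_fpkm[low] = np.round(rng.uniform(0, 4.9, size=int(low.sum())), 3)
    fpkm["fpkm"] = base_fpkm
    fpkm.loc[fpkm["gene_id"].isin(hits), "fpkm"] = np.round(
        rng.uniform(6, 60, size=len(hits)), 3
    )
    fpkm.loc[fpkm["gene_id"].isin(lowexpr_enriched), "fpkm"] = np.round(
        rng.uniform(0, 4.5, size=len(lowexpr_enriched)), 3
    )
    fpkm.to_csv(outdir / "screen_fpkm.tsv", sep="\t", index=False)

    truth = pd.DataFrame(
        {
            "gene": sorted(enriched),
            "kind": [
                "hit"
                if g in hits
                else ("olfactory_decoy" if g in olf_enriched else "lowexpr_decoy")
                for g in sorted(enriched)
            ],
        }
    )
    truth.to_csv(outdir / "truth_screen.tsv", sep="\t", index=False)
    return truth


def sim_rna(cfg: SimConfig, outdir: str | Path) -> pd.DataFrame:
    """RNA count matrix (control vs knockdown) with planted upregulated genes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(4)
    n = cfg.rna_n_genes
    genes = [f"r{i:04d}" for i in range(n)]
    up = set(genes[: cfg.rna_n_up])
    mean = rng.lognormal(cfg.rna_mean_log, 1.0, size=n)
    r = 1.0 / cfg.rna_dispersion
    cols = {}
    for s in range(cfg.rna_n_per_group):
        cols[f"ctrl{s + 1}"] = rng.poisson(rng.gamma(r, mean / r))
    kd_mean = mean * np.where(np.isin(genes, list(up)), cfg.rna_fold, 1.0)
    for s in range(cfg.rna_n_per_group):
        cols[f"kd{s + 1}"] = rng.poisson(rng.gamma(r, kd_mean / r))
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    counts.to_csv(outdir / "rna_counts.tsv", sep="\t")
    lengths = pd.Series(
        rng.integers(500, 5000, size=n), index=counts.index, name="length_bp"
    )
    lengths.to_csv(outdir / "rna_gene_lengths.tsv", sep="\t")
    truth = pd.DataFrame({"gene": genes, "planted_up": [g in up for g in genes]})
    truth.to_csv(outdir / "truth_rna.tsv", sep="\t", index=False)
    return truth


def sim_bisulfite(cfg: SimConfig, outdir: str | Path) -> pd.DataFrame:
    """Bisulfite coverage calls with planted region levels and conversion error.

    Each region holds ``bis_cpgs_per_region`` CpGs; every CpG receives
    independent plus- and minus-strand calls at half the nominal depth.
    Unmethylated cytosines escape conversion with probability
    ``1 - bis_conversion`` and then read as methylated.  Fill-in
    positions (MspI end repair, always unmethylated) are emitted
    separately for the conversion-efficiency estimate.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(5)
    conv = cfg.bis_conversion
    cov_rows = []
    region_rows = []
    cpg_sites = []
    chrom = "chrM1"
    pos = 1000
    rid = 0
    for level in cfg.bis_region_levels:
        for _ in range(cfg.bis_regions_per_level):
            start = pos
            for _ in range(cfg.bis_cpgs_per_region):
                cpg_sites.append(pos)
                p_obs = level + (1.0 - level) * (1.0 - conv)
                for strand_off in (0, 1):  # plus C, then minus C at pos+1
                    d = int(rng.poisson(cfg.bis_depth / 2.0))
                    if d == 0:
                        continue
                    m = int(rng.binomial(d, p_obs))
                    cov_rows.append((chrom, pos + strand_off, m, d - m))
                pos += 30
            region_rows.append((chrom, start - 10, pos + 10, f"region{rid:03d}", level))
            rid += 1
            pos += 500
    cov = pd.DataFrame(cov_rows, columns=["chrom", "pos", "n_meth", "n_unmeth"])
    out = pd.DataFrame(
        {
            "chrom": cov["chrom"],
            "start": cov["pos"],
            "end": cov["pos"] + 1,
            "percent": (100 * cov["n_meth"] / (cov["n_meth"] + cov["n_unmeth"])).round(3),
            "n_meth": cov["n_meth"],
            "n_unmeth": cov["n_unmeth"],
        }
    )
    out.to_csv(outdir / "bisulfite.cov.tsv", sep="\t", index=False, header=False)

    with open(outdir / "cpg_sites.bed", "w") as fh:
        for p in cpg_sites:
            fh.write(f"{chrom}\t{p}\t{p + 2}\n")

    # fill-in cytosines: unmethylated by construction
    n_c = int(rng.binomial(cfg.bis_n_fill_in, 1.0 - conv))
    fill = pd.DataFrame(
        {
            "chrom": [chrom],
            "pos": [0],
            "n_meth": [n_c],
            "n_unmeth": [cfg.bis_n_fill_in - n_c],
        }
    )
    fill.to_csv(outdir / "fill_in_calls.tsv", sep="\t", index=False)

    regions = pd.DataFrame(
        region_rows, columns=["chrom", "start", "end", "name", "planted_level"]
    )
    regions[["chrom", "start", "end", "name"]].to_csv(
        outdir / "bis_regions.bed", sep="\t", index=False, header=False
    )
    regions.to_csv(outdir / "truth_bisulfite.tsv", sep="\t", index=False)
    return regions


def sim_te(cfg: SimConfig, outdir: str | Path) -> pd.DataFrame:
    """SAM alignments over planted TE copies, one file per sample, plus truth.

    Reads multi-map within their family with multiplicity drawn from
    ``te_multimap_probs``; every alignment carries an NH tag.  The
    planted family is upregulated ``te_fold``-fold in the knockdown
    group.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(6)
    chrom = "chrTE"
    copy_len, n_copies = cfg.te_copy_length, cfg.te_copies_per_family
    gap = 200
    ann_rows = []
    copy_starts: dict[str, list[int]] = {}
    pos = 100
    for fam in cfg.te_families:
        copy_starts[fam] = []
        for c in range(n_copies):
            ann_rows.append((chrom, pos, pos + copy_len, "+", f"{fam}_c{c}", fam))
            copy_starts[fam].append(pos)
            pos += copy_len + gap
    chrom_len = pos + 1000
    ann = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "strand", "element_name", "family_id"]
    )
    ann.to_csv(outdir / "te_annotation.tsv", sep="\t", index=False)

    mult = sorted(cfg.te_multimap_probs.items())
    ks = np.array([m[0] for m in mult])
    kp = np.array([m[1] for m in mult], dtype=float)
    kp /= kp.sum()
    read_len = 80
    r = 1.0 / cfg.te_dispersion

    samples = [f"ctrl{i + 1}" for i in range(cfg.te_n_per_group)] + [
        f"kd{i + 1}" for i in range(cfg.te_n_per_group)
    ]
    truth_counts = {}
    for sample in samples:
        is_kd = sample.startswith("kd")
        lines = [f"@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{chrom_len}"]
        counts = {}
        ridx = 0
        for fam in cfg.te_families:
            mean = cfg.te_reads_per_family
            if is_kd and fam == cfg.te_planted_family:
                mean *= cfg.te_fold
            n_reads = int(rng.poisson(rng.gamma(r, mean / r)))
            counts[fam] = n_reads
            for _ in range(n_reads):
                k = int(rng.choice(ks, p=kp))
                k = min(k, n_copies)
                copies = rng.choice(n_copies, size=k, replace=False)
                offset = int(rng.integers(0, copy_len - read_len))
                qname = f"{sample}_{fam}_{ridx}"
                for j, c in enumerate(sorted(copies)):
                    flag = 0 if j == 0 else 256
                    p1 = copy_starts[fam][c] + offset + 1  # SAM is 1-based
                    lines.append(
                        f"{qname}\t{flag}\t{chrom}\t{p1}\t30\t{read_len}M\t*\t0\t0\t"
                        f"{'A' * read_len}\t*\tNH:i:{k}"
                    )
                ridx += 1
        truth_counts[sample] = counts
        with open(outdir / f"te_{sample}.sam", "w") as fh:
            fh.write("\n".join(lines) + "\n")

    truth = pd.DataFrame(truth_counts)
    truth.index.name = "family_id"
    truth.to_csv(outdir / "truth_te.tsv", sep="\t")
    return truth


def sim_ipms(cfg: SimConfig, outdir: str | Path) -> pd.DataFrame:
    """Spectral-count matrix (WT IP vs KO IP) with planted true partners.

    Background proteins share a common NB law in both groups; true
    partners are enriched ``ipms_enrichment``-fold in the WT IP and drop
    to ``ipms_partner_ko_mean`` in the knockout control.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(7)
    n = cfg.ipms_n_proteins
    proteins = [f"P{i:04d}" for i in range(n)]
    partners = set(proteins[: cfg.ipms_n_partners])
    base = rng.lognormal(np.log(cfg.ipms_background_mean), 0.8, size=n)
    r = 1.0 / cfg.ipms_dispersion
    cols = {}
    for s in range(cfg.ipms_n_per_group):
        mean = np.where(np.isin(proteins, list(partners)), base * cfg.ipms_enrichment, base)
        cols[f"WT{s + 1}"] = rng.poisson(rng.gamma(r, mean / r))
    for s in range(cfg.ipms_n_per_group):
        mean = np.where(
            np.isin(proteins, list(partners)), cfg.ipms_partner_ko_mean, base
        )
        cols[f"KO{s + 1}"] = rng.poisson(rng.gamma(r, mean / r))
    counts = pd.DataFrame(cols, index=pd.Index(proteins, name="protein"))
    counts.to_csv(outdir / "ipms_counts.tsv", sep="\t")
    groups = pd.DataFrame(
        {
            "sample": counts.columns,
            "group": ["WT"] * cfg.ipms_n_per_group + ["KO"] * cfg.ipms_n_per_group,
        }
    )
    groups.to_csv(outdir / "ipms_groups.tsv", sep="\t", index=False)
    truth = pd.DataFrame(
        {"protein": proteins, "is_partner": [p in partners for p in proteins]}
    )
    truth.to_csv(outdir / "truth_ipms.tsv", sep="\t", index=False)
    return truth


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Run every generator into subdirectories of *outdir*; returns truth tables."""
    outdir = Path(outdir)
    truth = {}
    truth["promoters"] = sim_genome(cfg, outdir / "genome")
    truth["marks"] = sim_tracks(cfg, truth["promoters"], outdir / "tracks")
    truth["screen"] = sim_screen(cfg, outdir / "screen")
    truth["rna"] = sim_rna(cfg, outdir / "rna")
    truth["bisulfite"] = sim_bisulfite(cfg, outdir / "bisulfite")
    truth["te"] = sim_te(cfg, outdir / "te")
    truth["ipms"] = sim_ipms(cfg, outdir / "ipms")
    return truth
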