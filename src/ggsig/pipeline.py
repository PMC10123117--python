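"""Stage orchestration: one config, plain-TSV outputs, a run manifest.

Stages are pure given their inputs; the manifest records the package
version, a hash of the resolved config and per-stage output row counts,
so reruns are comparable byte-for-byte apart from the manifest
timestamp.  Missing inputs for any requested stage abort the run before
any stage executes, listing every missing file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import chromatin_signature as cs
from . import geneset_stats as gs
from . import ipms_stats
from . import methylation as meth
from . import promoter_model as pm
from . import screen_select as ss
from . import te_quant

logger = logging.getLogger(__name__)

STAGE_ORDER = ["promoters", "signature", "screen", "rna", "te", "methylation", "ipms"]

_STAGE_INPUTS = {
    "promoters": ["genome", "annotation"],
    "signature": ["fpkm", "targets"],
    "screen": ["full", "fpkm"],
    "rna": ["counts"],
    "te": ["annotation", "sams"],
    "methylation": ["coverage", "regions"],
    "ipms": ["counts", "groups"],
}


class PipelineError(Exception):
    pass


def _missing_inputs(cfg: dict, stage: str) -> list[str]:
    missing = []
    section = cfg.get(stage, {})
    for key in _STAGE_INPUTS[stage]:
        path = section.get(key)
        if path is None:
            missing.append(f"{stage}.{key} (not configured)")
        elif isinstance(path, list):
            missing += [f"{stage}.{key}: {p}" for p in path if not Path(p).exists()]
        elif not Path(path).exists():
            missing.append(f"{stage}.{key}: {path}")
    return missing


def run_pipeline(
    config: dict | str, outdir: str | Path, stages: list[str] | None = None
) -> dict:
    """Run the configured stages into *outdir*; returns the manifest dict."""
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    unknown = set(stages or []) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    requested = [
        s for s in STAGE_ORDER if (stages is None or s in stages) and s in config
    ]

    missing: list[str] = []
    for stage in requested:
        missing += _missing_inputs(config, stage)
        if stage == "signature" and "promoters" not in requested:
            ptab = config["signature"].get("promoter_table", outdir / "promoters.tsv")
            if not Path(ptab).exists():
                missing.append(f"signature.promoter_table: {ptab}")
    if missing:
        raise PipelineError("missing inputs: " + "; ".join(missing))

    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }
    runners = {
        "promoters": _stage_promoters,
        "signature": _stage_signature,
        "screen": _stage_screen,
        "rna": _stage_rna,
        "te": _stage_te,
        "methylation": _stage_methylation,
        "ipms": _stage_ipms,
    }
    for stage in requested:
        logger.info("running stage %s", stage)
        manifest["stages"][stage] = runners[stage](config[stage], outdir)

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _stage_promoters(cfg: dict, outdir: Path) -> dict:
    annotation = pm.read_tss_table(cfg["annotation"])
    cgi = pm.read_cgi_bed(cfg["cgi"]) if cfg.get("cgi") else None
    records = pm.build_promoters(annotation, cfg["genome"], cgi)
    pm.write_promoter_table(records, str(outdir / "promoters.tsv"))
    counts = pd.Series([r.cls for r in records]).value_counts().to_dict()
    return {"n_promoters": len(records), "classes": counts}


def _stage_signature(cfg: dict, outdir: Path) -> dict:
    promoters = pm.read_promoter_table(
        str(cfg.get("promoter_table", outdir / "promoters.tsv"))
    )
    target_genes = {line.strip() for line in open(cfg["targets"]) if line.strip()}
    hcp = [p for p in promoters if p.cls == "HCP"]
    target_ids = [p.promoter_id for p in hcp if p.gene_id in target_genes]
    fpkm = pd.read_csv(cfg["fpkm"], sep="\t")
    background = cfg.get("background", "inactive")
    if background == "inactive":
        background_ids = sorted(cs.inactive_set(fpkm, promoters))
        kind = "inactive_HCP"
    else:
        background_ids = [p.promoter_id for p in hcp]
        kind = "all_HCP"

    track_paths = [Path(p) for p in cfg.get("tracks", [])] or sorted(
        Path(cfg.get("tracks_dir", ".")).glob("*.bedGraph")
    )
    if not track_paths:
        raise PipelineError("signature: no bedGraph tracks found")
    flank = int(cfg.get("flank_bp", cs.DEFAULT_FLANK_BP))
    heat_flank = int(cfg.get("heatmap_flank_bp", 1000))
    scores, heat_profiles = [], []
    for path in track_paths:
        track = cs.BedGraphTrack.read(str(path))
        profile = cs.tss_profile(track, hcp, flank_bp=flank, dataset_id=path.stem)
        scores.append(cs.set_enrichment(profile, target_ids, background_ids, background_kind=kind))
        heat_profiles.append(
            cs.tss_profile(track, hcp, flank_bp=heat_flank, dataset_id=path.stem)
        )
    ranking = cs.rank_datasets(scores)
    ranking.to_csv(outdir / "signature_ranking.tsv", sep="\t", index=False)
    heat = cs.heatmap_matrix(
        heat_profiles, target_ids, background_ids, bin_bp=int(cfg.get("bin_bp", 20))
    )
    heat.to_csv(outdir / "signature_heatmap.tsv", sep="\t")
    return {
        "n_datasets": len(scores),
        "n_targets": len(target_ids),
        "n_background": len(background_ids),
    }


def _stage_screen(cfg: dict, outdir: Path) -> dict:
    full = ss.read_gene_summary(cfg["full"], "full")
    pairwise = [ss.read_gene_summary(p, Path(p).stem) for p in cfg.get("pairwise", [])]
    fpkm_df = pd.read_csv(cfg["fpkm"], sep="\t")
    fpkm = dict(zip(fpkm_df.iloc[:, 0], fpkm_df.iloc[:, 1]))
    olfactory = None
    if cfg.get("olfactory"):
        olfactory = {l.strip() for l in open(cfg["olfactory"]) if l.strip()}
    result = ss.select_candidates(
        full,
        pairwise,
        fpkm,
        olfactory=olfactory,
        p_max=float(cfg.get("p_max", ss.DEFAULT_P_MAX)),
    )
    result.to_frame().to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    result.removals_frame().to_csv(
        outdir / "candidate_removals.tsv", sep="\t", index=False
    )
    return {"n_candidates": len(result.genes), "n_removed": len(result.removed)}


def _groups_from_columns(columns, cfg: dict) -> tuple[list[str], str, str]:
    num = cfg.get("numerator", "kd")
    den = cfg.get("denominator", "ctrl")
    labels = [
        num if c.startswith(num) else den if c.startswith(den) else c for c in columns
    ]
    return labels, num, den


def _stage_rna(cfg: dict, outdir: Path) -> dict:
    counts = pd.read_csv(cfg["counts"], sep="\t", index_col=0)
    labels, num, den = _groups_from_columns(counts.columns, cfg)
    stats = ipms_stats.nb_test(counts, labels, num, den).rename(
        columns={"protein": "gene"}
    )
    stats.to_csv(outdir / "rna_de.tsv", sep="\t", index=False)
    up, down = gs.de_filter(
        stats,
        fc_min=float(cfg.get("fc_min", 2.0)),
        padj_max=float(cfg.get("padj_max", 0.001)),
    )
    pd.Series(sorted(up)).to_csv(outdir / "rna_up.txt", index=False, header=False)
    pd.Series(sorted(down)).to_csv(outdir / "rna_down.txt", index=False, header=False)
    return {"n_genes": len(stats), "n_up": len(up), "n_down": len(down)}


def _stage_te(cfg: dict, outdir: Path) -> dict:
    annotation = te_quant.TEAnnotation.read(cfg["annotation"])
    sam_paths = {Path(p).stem.replace("te_", ""): p for p in cfg["sams"]}
    counts = te_quant.count_samples(sam_paths, annotation)
    counts.to_csv(outdir / "te_counts.tsv", sep="\t", float_format="%.4f")
    labels, num, den = _groups_from_columns(counts.columns, cfg)
    stats = te_quant.te_differential(counts, labels, num, den)
    stats.to_csv(outdir / "te_de.tsv", sep="\t", index=False)
    return {"n_families": len(counts), "n_samples": int(counts.shape[1])}


def _split_strands(calls: pd.DataFrame, cpg_bed: str | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign calls to strands: by a reference CpG BED of plus-strand C
    positions when given, else by pairing (a call at p with a call at p-1
    present is taken as the minus-strand G of that CpG)."""
    if cpg_bed:
        cpg = pd.read_csv(
            cpg_bed, sep="\t", header=None, names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
        plus_pos = set(zip(cpg["chrom"], cpg["start"]))
        is_plus = pd.Series(
            [(c, p) in plus_pos for c, p in zip(calls["chrom"], calls["pos"])],
            index=calls.index,
        )
    else:
        present = set(zip(calls["chrom"], calls["pos"]))
        is_plus = pd.Series(
            [(c, p - 1) not in present for c, p in zip(calls["chrom"], calls["pos"])],
            index=calls.index,
        )
    return calls[is_plus], calls[~is_plus]


def _stage_methylation(cfg: dict, outdir: Path) -> dict:
    calls = meth.read_coverage(cfg["coverage"])
    plus, minus = _split_strands(calls, cfg.get("cpg_bed"))
    sites = meth.merge_strands(plus, minus)
    sites.to_csv(outdir / "meth_sites.tsv", sep="\t", index=False, float_format="%.6g")
    regions = pd.read_csv(
        cfg["regions"], sep="\t", header=None, names=["chrom", "start", "end", "name"],
        dtype={"chrom": str},
    )
    region_table = meth.region_methylation(sites, regions)
    region_table.to_csv(
        outdir / "meth_regions.tsv", sep="\t", index=False, float_format="%.6g"
    )
    summary: dict[str, float] = {}
    if cfg.get("fill_in"):
        fill = pd.read_csv(cfg["fill_in"], sep="\t")
        summary["conversion_efficiency"] = meth.conversion_efficiency(fill)
    if cfg.get("cgi"):
        cgi = pd.read_csv(
            cfg["cgi"], sep="\t", header=None, names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
        meth.cgi_partition_summary(sites, cgi).to_csv(
            outdir / "meth_cgi_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
    if summary:
        pd.Series(summary).to_csv(
            outdir / "meth_summary.tsv", sep="\t", header=False, float_format="%.6g"
        )
    return {
        "n_sites": len(sites),
        "n_passing": int(sites["passes_depth"].sum()),
        "n_regions": len(region_table),
        **{k: float(v) for k, v in summary.items()},
    }


def _stage_ipms(cfg: dict, outdir: Path) -> dict:
    counts = pd.read_csv(cfg["counts"], sep="\t", index_col=0)
    groups = pd.read_csv(cfg["groups"], sep="\t")
    labels = groups.set_index("sample")["group"].reindex(counts.columns).tolist()
    stats = ipms_stats.nb_test(
        counts, labels, cfg.get("numerator", "WT"), cfg.get("denominator", "KO")
    )
    called = ipms_stats.call_interactors(stats)
    stats["called"] = stats["protein"].isin(called)
    stats.to_csv(outdir / "ipms_stats.tsv", sep="\t", index=False)
    pd.Series(sorted(called)).to_csv(
        outdir / "ipms_interactors.txt", index=False, header=False
    )
    return {"n_proteins": len(stats), "n_called": len(called)}


def default_config_for(simdir: str | Path) -> dict:
    """Pipeline config wired to the file layout of :func:`synthetic_data.simulate_all`."""
    d = Path(simdir)
    return {
        "promoters": {
            "genome": str(d / "genome/genome.fa"),
            "annotation": str(d / "genome/tss.bed"),
            "cgi": str(d / "genome/cgi.bed"),
        },
        "signature": {
            "tracks_dir": str(d / "tracks"),
            "fpkm": str(d / "genome/fpkm.tsv"),
            "targets": str(d / "genome/targets.txt"),
            "background": "inactive",
        },
        "screen": {
            "full": str(d / "screen/gene_summary_full.tsv"),
            "pairwise": [
                str(p) for p in sorted((d / "screen").glob("gene_summary_rep*.tsv"))
            ],
            "fpkm": str(d / "screen/screen_fpkm.tsv"),
        },
        "rna": {"counts": str(d / "rna/rna_counts.tsv")},
        "te": {
            "annotation": str(d / "te/te_annotation.tsv"),
            "sams": [str(p) for p in sorted((d / "te").glob("te_*.sam"))],
        },
        "methylation": {
            "coverage": str(d / "bisulfite/bisulfite.cov.tsv"),
            "regions": str(d / "bisulfite/bis_regions.bed"),
            "fill_in": str(d / "bisulfite/fill_in_calls.tsv"),
            "cpg_bed": str(d / "bisulfite/cpg_sites.bed"),
        },
        "ipms": {
            "counts": str(d / "ipms/ipms_counts.tsv"),
            "groups": str(d / "ipms/ipms_groups.tsv"),
        },
    }
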