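"""Config-driven orchestration of the end-to-end analysis.

Stages run in order filter -> annotate -> window stats -> LD -> sweeps ->
HS/LS divergence -> BLUP -> GWAS -> allele effects, each writing a TSV/JSON
that later stages (and reruns) can consume, plus a manifest of input hashes,
parameters and output hashes. Reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .formats import (filter_sites, read_fasta, read_gff, read_groups,
                      read_phenotypes, read_vcf)
from .annotate import annotate_sites, annotation_summary, annotation_table, ts_tv_ratio
from .popstats import make_windows, window_stats
from .ld import half_decay_distance, ld_decay_curve
from .sweeps import (call_sweep_regions, common_selected_genes, genes_in_regions,
                     regions_table, trait_group_split, window_contrast)
from .gwas import (MixedModelGWAS, blup_phenotype, phenotype_summary)
from .alleles import allele_effect, allele_effects_table

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    vcf: str
    outdir: str
    gff: str | None = None
    fasta: str | None = None
    phenotypes: str | None = None
    groups: str | None = None
    trait: str = "sesamin"
    maf_min: float = 0.05
    missing_max: float = 0.2
    depth_min: int = 8
    window_size: int = 10_000
    fst_min: float = 0.45
    log2_ratio_min: float = 2.5
    sweep_mode: str = "fixed"
    merge_gap: int = 1
    background_group: str | None = None
    focal_groups: list[str] = field(default_factory=list)
    high_min: float = 6.0
    low_max: float = 1.0
    gwas_threshold: float = 6.0
    ld_window_bp: int = 89_000
    ld_max_dist: int = 500_000
    ld_bin_bp: int = 1000
    run_gwas: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("vcf", "gff", "fasta", "phenotypes", "groups"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        if self.run_gwas and self.phenotypes is None:
            raise ValueError("GWAS enabled but no phenotype file configured")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params": {k: v for k, v in asdict(config).items()},
        "inputs": {}, "outputs": {},
    }
    for key in ("vcf", "gff", "fasta", "phenotypes", "groups"):
        p = getattr(config, key)
        if p is not None:
            manifest["inputs"][key] = _sha256(p)
    outputs: dict[str, Path] = {}

    def stage(name):
        log.info("stage: %s", name)

    # ---- filter -----------------------------------------------------------
    stage("filter")
    gm_raw = read_vcf(config.vcf)
    gm, report = filter_sites(gm_raw, config.maf_min, config.missing_max,
                              config.depth_min)
    _write_json(report.as_dict(), outdir / "filter_report.json")
    outputs["filter_report"] = outdir / "filter_report.json"

    genes = read_gff(config.gff) if config.gff else []
    ref = read_fasta(config.fasta) if config.fasta else None
    if ref is not None:
        missing = sorted(set(gm.sites.chrom.unique()) - set(ref))
        if missing:
            raise ValueError(f"VCF chromosomes absent from FASTA: {missing}")
    groups = read_groups(config.groups) if config.groups else {}

    # ---- annotate ---------------------------------------------------------
    if genes:
        stage("annotate")
        anns = annotate_sites(gm, genes, ref)
        _write_tsv(annotation_table(anns), outdir / "annotation.tsv")
        outputs["annotation"] = outdir / "annotation.tsv"
        summ = annotation_summary(anns)
        summ["ts_tv_ratio"] = ts_tv_ratio([gm.site_at(j) for j in range(gm.n_sites)])
        _write_json(summ, outdir / "annotation_summary.json")
        outputs["annotation_summary"] = outdir / "annotation_summary.json"

    # ---- window stats -----------------------------------------------------
    stats_df = None
    if groups:
        stage("window stats")
        stats_df = window_stats(gm, groups, window_size=config.window_size)
        _write_tsv(stats_df, outdir / "window_stats.tsv")
        outputs["window_stats"] = outdir / "window_stats.tsv"

    # ---- LD ---------------------------------------------------------------
    stage("ld")
    curve = ld_decay_curve(gm, max_dist=config.ld_max_dist,
                           bin_bp=config.ld_bin_bp, seed=config.seed)
    _write_tsv(curve.to_frame(), outdir / "ld_curve.tsv")
    outputs["ld_curve"] = outdir / "ld_curve.tsv"
    _write_json({"max_r2": curve.max_r2,
                 "half_decay_bp": half_decay_distance(curve)},
                outdir / "ld_summary.json")
    outputs["ld_summary"] = outdir / "ld_summary.json"

    # ---- sweeps -----------------------------------------------------------
    gene_sets = {}
    if stats_df is not None and config.background_group and config.focal_groups:
        stage("sweeps")
        all_regions = []
        for focal in config.focal_groups:
            contrasts = window_contrast(stats_df, focal, config.background_group)
            regions = call_sweep_regions(
                contrasts, config.fst_min, config.log2_ratio_min,
                mode=config.sweep_mode, merge_gap=config.merge_gap,
                window_size=config.window_size)
            regions, union = genes_in_regions(regions, genes)
            gene_sets[focal] = union
            all_regions.extend(regions)
        _write_tsv(regions_table(all_regions), outdir / "sweep_regions.tsv")
        outputs["sweep_regions"] = outdir / "sweep_regions.tsv"
        if len(gene_sets) >= 2:
            common = common_selected_genes(*gene_sets.values())
            _write_json({"per_group": {k: sorted(v) for k, v in gene_sets.items()},
                         "common": common}, outdir / "venn.json")
            outputs["venn"] = outdir / "venn.json"

    # ---- phenotypes, BLUP, HS/LS scan, GWAS, alleles ----------------------
    if config.phenotypes:
        stage("blup")
        pt = read_phenotypes(config.phenotypes)
        _write_tsv(phenotype_summary(pt, config.trait),
                   outdir / "phenotype_summary.tsv")
        outputs["phenotype_summary"] = outdir / "phenotype_summary.tsv"
        blups = blup_phenotype(pt, config.trait)
        blups.rename("blup").to_frame().reset_index().to_csv(
            outdir / "blup.csv", index=False, float_format=FLOAT_FORMAT)
        outputs["blup"] = outdir / "blup.csv"

        stage("hs/ls divergence")
        high, low = trait_group_split(blups, config.high_min, config.low_max)
        hsls = {"high": high, "low": low}
        _write_json(hsls, outdir / "trait_groups.json")
        outputs["trait_groups"] = outdir / "trait_groups.json"
        if len(high) >= 10 and len(low) >= 10:
            hl_stats = window_stats(
                gm, {**{s: "HS" for s in high}, **{s: "LS" for s in low}},
                window_size=config.window_size)
            contrasts = window_contrast(hl_stats, "HS", "LS")
            regions = call_sweep_regions(
                contrasts, config.fst_min, config.log2_ratio_min,
                mode=config.sweep_mode, merge_gap=config.merge_gap,
                window_size=config.window_size)
            regions, _ = genes_in_regions(regions, genes)
            _write_tsv(regions_table(regions), outdir / "hsls_regions.tsv")
            outputs["hsls_regions"] = outdir / "hsls_regions.tsv"

        if config.run_gwas:
            stage("gwas")
            present = [s for s in gm.samples if s in blups.index]
            gm_g = gm.take_samples(present) if len(present) < gm.n_samples else gm
            res = MixedModelGWAS(gm_g, blups).fit()
            _write_tsv(res.table.drop(columns=["flag_collinear"]),
                       outdir / "gwas_assoc.tsv")
            outputs["gwas_assoc"] = outdir / "gwas_assoc.tsv"
            loci = res.significant_loci(config.gwas_threshold, config.ld_window_bp)
            _write_tsv(loci, outdir / "gwas_loci.tsv")
            outputs["gwas_loci"] = outdir / "gwas_loci.tsv"
            if genes:
                _write_tsv(res.candidate_genes(genes, config.gwas_threshold,
                                               config.ld_window_bp),
                           outdir / "candidate_genes.tsv")
                outputs["candidate_genes"] = outdir / "candidate_genes.tsv"
            _write_tsv(res.qq_data(), outdir / "qq.tsv")
            outputs["qq"] = outdir / "qq.tsv"
            _write_json({"lambda_gc": res.lambda_gc,
                         "sigma_g2": res.null.sigma_g2,
                         "sigma_e2": res.null.sigma_e2,
                         "heritability": res.null.heritability},
                        outdir / "gwas_model.json")
            outputs["gwas_model"] = outdir / "gwas_model.json"

            stage("allele effects")
            effects = []
            site_ids = {gm_g.site_at(j).locus_id: j for j in range(gm_g.n_sites)}
            for _, row in loci.iterrows():
                j = site_ids.get(row.id)
                if j is not None:
                    effects.append(allele_effect(gm_g, j, blups))
            _write_tsv(allele_effects_table(effects), outdir / "allele_effects.tsv")
            outputs["allele_effects"] = outdir / "allele_effects.tsv"

    for name, path in outputs.items():
        manifest["outputs"][name] = _sha256(path)
    _write_json(manifest, outdir / "manifest.json")
    return manifest
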