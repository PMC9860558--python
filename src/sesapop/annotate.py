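"""SNP annotation: genomic-context classes, coding effects, and summary ratios.

Region classes follow the exclusive-precedence convention
exonic > splicing > intronic > upstream/downstream > intergenic, with a
1 kb flank for up/downstream and a 2 bp splice window inside the intron.
Coding effects use the standard genetic code on the coding strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .formats import GeneModel, GenotypeMatrix, VariantSite

REGION_PRECEDENCE = ["exonic", "splicing", "intronic", "upstream", "downstream",
                     "intergenic"]
DEFAULT_FLANK = 1000
SPLICE_WINDOW = 2

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SiteAnnotation:
    site: VariantSite
    region_class: str
    gene_id: str | None = None
    coding_effect: str = "n/a"
    aa_change: str = ""


def _classes_for_gene(pos: int, gene: GeneModel, flank: int) -> list[str]:
    """All region classes the position earns from one gene (may be several)."""
    out = []
    if gene.start <= pos < gene.end:
        in_exon = any(s <= pos < e for s, e in gene.exons)
        if in_exon:
            out.append("exonic")
        else:
            # inside the gene span but not in an exon: intron
            near_boundary = any(
                0 < s - pos <= SPLICE_WINDOW or 0 < pos - (e - 1) <= SPLICE_WINDOW
                for s, e in gene.exons)
            out.append("splicing" if near_boundary else "intronic")
    else:
        before = gene.start - flank <= pos < gene.start
        after = gene.end <= pos < gene.end + flank
        if before:
            out.append("upstream" if gene.strand == "+" else "downstream")
        if after:
            out.append("downstream" if gene.strand == "+" else "upstream")
    return out


def classify_region(site: VariantSite, genes: list[GeneModel],
                    flank: int = DEFAULT_FLANK, all_overlaps: bool = False):
    """Classify one SNP against all gene models (precedence, or all classes).

    ``all_overlaps=True`` returns the full set of (class, gene_id) hits for
    debugging; the default returns the single highest-precedence class and
    the gene that granted it (None for intergenic).
    """
    hits = []
    for gene in genes:
        if gene.chrom != site.chrom:
            continue
        if not (gene.start - flank <= site.pos < gene.end + flank):
            continue
        for cls in _classes_for_gene(site.pos, gene, flank):
            hits.append((cls, gene.gene_id))
    if all_overlaps:
        return hits or [("intergenic", None)]
    if not hits:
        return "intergenic", None
    hits.sort(key=lambda h: REGION_PRECEDENCE.index(h[0]))
    return hits[0]


def coding_effect(site: VariantSite, gene: GeneModel, ref_seq: str,
                  ) -> tuple[str, str]:
    """Effect of a CDS SNP: synonymous / nonsynonymous / stop_gain / stop_loss.

    The codon is located on the coding strand (reverse complement for minus
    strand genes); amino acids are reported three-letter as "Thr->Lys".
    Returns ("n/a", "") with a warning for an incomplete terminal codon.
    """
    cds = sorted(gene.cds)
    if not any(s <= site.pos < e for s, e, _ in cds):
        raise ValueError(f"{site.locus_id} not in CDS of {gene.gene_id}")
    if ref_seq[site.pos] != site.ref:
        raise ValueError(
            f"REF mismatch at {site.locus_id}: VCF {site.ref}, FASTA {ref_seq[site.pos]}")
    # assemble the CDS on the plus strand and locate the site's offset in it
    parts, offset = [], None
    acc = 0
    for s, e, _ in cds:
        parts.append(ref_seq[s:e])
        if s <= site.pos < e:
            offset = acc + (site.pos - s)
        acc += e - s
    plus_cds = "".join(parts)
    L = len(plus_cds)
    if gene.strand == "+":
        coding = plus_cds
        cpos = offset
        ref_base, alt_base = site.ref, site.alt
    else:
        coding = plus_cds.translate(_COMPLEMENT)[::-1]
        cpos = L - 1 - offset
        ref_base = site.ref.translate(_COMPLEMENT)
        alt_base = site.alt.translate(_COMPLEMENT)
    if coding[cpos] != ref_base:
        raise ValueError(f"internal CDS assembly error at {site.locus_id}")
    codon_idx = cpos // 3
    if (codon_idx + 1) * 3 > L:
        warnings.warn(f"incomplete terminal codon in {gene.gene_id}", stacklevel=2)
        return "n/a", ""
    codon = coding[codon_idx * 3:(codon_idx + 1) * 3]
    within = cpos % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    change = f"{_aa3(aa_ref)}->{_aa3(aa_alt)}"
    if aa_ref == aa_alt:
        return "synonymous", change
    if aa_alt == "*":
        return "stop_gain", change
    if aa_ref == "*":
        return "stop_loss", change
    return "nonsynonymous", change


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def annotate_sites(gm: GenotypeMatrix, genes: list[GeneModel],
                   ref_seqs: dict[str, str] | None = None,
                   flank: int = DEFAULT_FLANK) -> list[SiteAnnotation]:
    """Annotate every site in the matrix; coding effects need ``ref_seqs``."""
    gene_by_id = {g.gene_id: g for g in genes}
    out = []
    for j in range(gm.n_sites):
        site = gm.site_at(j)
        cls, gene_id = classify_region(site, genes, flank)
        effect, aa = "n/a", ""
        if cls == "exonic" and gene_id is not None and ref_seqs is not None:
            gene = gene_by_id[gene_id]
            if any(s <= site.pos < e for s, e, _ in gene.cds):
                effect, aa = coding_effect(site, gene, ref_seqs[site.chrom])
        out.append(SiteAnnotation(site, cls, gene_id, effect, aa))
    return out


def ts_tv_ratio(sites) -> float:
    """Transition (A<->G, C<->T) to transversion ratio; inf when no transversions."""
    n_ts = n_tv = 0
    for s in sites:
        if {s.ref, s.alt} in ({"A", "G"}, {"C", "T"}):
            n_ts += 1
        else:
            n_tv += 1
    if n_tv == 0:
        warnings.warn("no transversions: Ts/Tv undefined", stacklevel=2)
        return float("inf")
    return n_ts / n_tv


def annotation_summary(annotations: list[SiteAnnotation]) -> dict:
    """Region-class proportions (summing to 1) and the NS/S ratio over CDS SNPs."""
    if not annotations:
        return {"n": 0, "region_proportions": {}, "ns_s_ratio": float("nan")}
    classes = pd.Series([a.region_class for a in annotations])
    props = (classes.value_counts(normalize=True)).to_dict()
    n_syn = sum(a.coding_effect == "synonymous" for a in annotations)
    n_non = sum(a.coding_effect == "nonsynonymous" for a in annotations)
    if n_syn == 0:
        if n_non:
            warnings.warn("no synonymous SNPs: NS/S ratio undefined", stacklevel=2)
        ratio = float("inf") if n_non else float("nan")
    else:
        ratio = n_non / n_syn
    return {"n": len(annotations), "region_proportions": props, "ns_s_ratio": ratio}


def annotation_table(annotations: list[SiteAnnotation]) -> pd.DataFrame:
    """TSV-ready table (1-based coordinates)."""
    return pd.DataFrame([{
        "chrom": a.site.chrom, "pos": a.site.pos + 1, "ref": a.site.ref,
        "alt": a.site.alt, "region_class": a.region_class,
        "gene_id": a.gene_id or "", "coding_effect": a.coding_effect,
        "aa_change": a.aa_change,
    } for a in annotations])
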