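"""Readers, writers, and site filtering for the standard formats the pipeline touches.

The VCF is the system of record. Internally all coordinates are 0-based
half-open; they are converted to 1-based inclusive at every I/O boundary
(VCF, GFF3, TSV outputs, ``Chr11-142842``-style locus ids).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing diploid call

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP. ``pos`` is 0-based; ``locus_id`` renders it 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos + 1}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos + 1}")

    @property
    def locus_id(self) -> str:
        return self.id or f"{self.chrom}-{self.pos + 1}"


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with one primary transcript.

    All intervals are 0-based half-open tuples sorted by genomic coordinate.
    ``cds`` carries (start, end, phase) with phase the number of bases to skip
    before the first complete codon of that segment on the coding strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        for s, e, _ in self.cds:
            if not any(s >= xs and e <= xe for xs, xe in self.exons):
                raise ValueError(f"CDS outside exons in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)

    def overlaps(self, start: int, end: int) -> bool:
        return self.chrom is not None and self.start < end and start < self.end


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites, diploid ALT-dosage codes {0,1,2} with -1 missing.

    ``sites`` is a DataFrame with columns chrom, pos (0-based), ref, alt, id,
    sorted by (chrom, pos). ``depth`` (optional) holds per-call read depths.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        if self.depth is not None and self.depth.shape != self.dosage.shape:
            raise ValueError("depth shape mismatch")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown sample {err.args[0]!r}") from None

    def dosage_float(self, sample_idx=None) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        out = d.astype(float)
        out[d == MISSING] = np.nan
        return out

    def alt_freq(self, sample_idx=None) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing calls (NaN if none)."""
        d = self.dosage_float(sample_idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def take_sites(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.copy(),
            dosage=self.dosage[idx].copy(),
            depth=None if self.depth is None else self.depth[idx].copy(),
        )

    def site_at(self, j: int) -> VariantSite:
        row = self.sites.iloc[j]
        return VariantSite(row.chrom, int(row.pos), row.ref, row.alt,
                           None if pd.isna(row.id) else row.id)

    def chrom_lengths(self) -> dict[str, int]:
        """Upper bound on chromosome length implied by the site table."""
        return {c: int(g.pos.max()) + 1 for c, g in self.sites.groupby("chrom", sort=False)}


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path) -> GenotypeMatrix:
    """Parse a VCF into a GenotypeMatrix, keeping biallelic SNPs only.

    Multi-allelic and non-SNP records are excluded with a logged count.
    Raises ``ValueError`` if the file declares no GT FORMAT field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    rows, dosages, depths = [], [], []
    has_depth = False
    n_excluded = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_excluded += 1
            continue
        gt = var.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        dos = np.where(gt == 3, MISSING, gt).astype(np.int8)
        dp = var.format("DP")
        if dp is not None:
            has_depth = True
            dp = dp.reshape(-1).astype(np.int32)
            dp[dp < 0] = 0
        else:
            dp = np.zeros(len(samples), dtype=np.int32)
        rows.append((var.CHROM, var.start, var.REF, var.ALT[0],
                     var.ID if var.ID not in (None, ".") else None))
        dosages.append(dos)
        depths.append(dp)
    if n_excluded:
        log.info("read_vcf(%s): excluded %d multi-allelic/non-SNP records", path, n_excluded)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosage = (np.array(dosages, dtype=np.int8).T if dosages
              else np.zeros((len(samples), 0), dtype=np.int8))
    depth = np.array(depths, dtype=np.int32).T if (depths and has_depth) else None
    gm = GenotypeMatrix(samples, sites, dosage, depth)
    order = np.lexsort((gm.sites.pos.to_numpy(), gm.sites.chrom.to_numpy()))
    if not np.array_equal(order, np.arange(gm.n_sites)):
        gm = gm.take_sites(order)
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Emit a minimal VCF v4.2 with GT (and DP when present)."""
    has_dp = gm.depth is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sesapop\n")
        contigs = contig_lengths or gm.chrom_lengths()
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        fmt = "GT:DP" if has_dp else "GT"
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            vid = row.id if isinstance(row.id, str) else "."
            if has_dp:
                calls = "\t".join(
                    f"{_GT_STR[int(gm.dosage[i, j])]}:{int(gm.depth[i, j])}"
                    for i in range(gm.n_samples))
            else:
                calls = "\t".join(_GT_STR[int(gm.dosage[i, j])] for i in range(gm.n_samples))
            fh.write(f"{row.chrom}\t{int(row.pos) + 1}\t{vid}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\t{fmt}\t{calls}\n")


# ---------------------------------------------------------------------------
# Site filtering

@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_dropped_maf: int
    n_dropped_missing: int
    n_calls_masked_depth: int
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input, "n_kept": self.n_kept,
            "n_dropped_maf": self.n_dropped_maf,
            "n_dropped_missing": self.n_dropped_missing,
            "n_calls_masked_depth": self.n_calls_masked_depth,
            "params": self.params,
        }


def filter_sites(gm: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.2,
                 depth_min: int = 8, depth_mode: str = "genotype",
                 ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the resequencing-panel site filters: depth >= 8x, MAF >= 0.05, missing <= 0.2.

    ``depth_mode="genotype"`` masks individual calls below ``depth_min`` before
    computing MAF and missingness (the conservative reading); ``"site_mean"``
    instead drops whole sites whose mean depth is below the threshold.
    """
    dosage = gm.dosage.copy()
    n_masked = 0
    site_keep = np.ones(gm.n_sites, dtype=bool)
    if gm.depth is not None and depth_min > 0:
        if depth_mode == "genotype":
            low = (gm.depth < depth_min) & (dosage != MISSING)
            n_masked = int(low.sum())
            dosage[low] = MISSING
        elif depth_mode == "site_mean":
            site_keep &= gm.depth.mean(axis=0) >= depth_min
        else:
            raise ValueError(f"unknown depth_mode {depth_mode!r}")
    work = GenotypeMatrix(gm.samples, gm.sites, dosage,
                          gm.depth.copy() if gm.depth is not None else None)
    miss = work.missing_rate()
    freq = work.alt_freq()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        maf = np.fmin(freq, 1.0 - freq)
    maf_ok = ~np.isnan(maf) & (maf >= maf_min)
    miss_ok = miss <= missing_max
    n_dropped_maf = int((site_keep & miss_ok & ~maf_ok).sum())
    n_dropped_missing = int((site_keep & ~miss_ok).sum())
    keep = site_keep & maf_ok & miss_ok
    out = work.take_sites(keep)
    if out.n_sites == 0:
        warnings.warn("all sites removed by filters", stacklevel=2)
    report = FilterReport(
        n_input=gm.n_sites, n_kept=out.n_sites,
        n_dropped_maf=n_dropped_maf, n_dropped_missing=n_dropped_missing,
        n_calls_masked_depth=n_masked,
        params={"maf_min": maf_min, "missing_max": missing_max,
                "depth_min": depth_min, "depth_mode": depth_mode},
    )
    log.info("filter_sites: kept %d/%d (maf -%d, missing -%d, %d calls depth-masked)",
             report.n_kept, report.n_input, n_dropped_maf, n_dropped_missing, n_masked)
    return out, report


# ---------------------------------------------------------------------------
# GFF3 / FASTA / tables

def read_gff(path) -> list[GeneModel]:
    """Load gene models from GFF3, selecting the longest-CDS transcript per gene."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    for c in db.features_of_type("CDS"):
        if not list(db.parents(c)):
            raise ValueError(f"CDS {c.id} has no parent feature")
    genes = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas if mrnas else [gene]
        best, best_len = None, -1
        for tr in parents:
            cds = sorted(db.children(tr, featuretype="CDS"), key=lambda f: f.start)
            total = sum(f.end - f.start + 1 for f in cds)
            if total > best_len:
                best, best_len = tr, total
        exons = sorted(db.children(best, featuretype="exon"), key=lambda f: f.start)
        cds = sorted(db.children(best, featuretype="CDS"), key=lambda f: f.start)
        if not exons and cds:
            exons = cds
        genes.append(GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start - 1,
            end=gene.end,
            exons=tuple((f.start - 1, f.end) for f in exons),
            cds=tuple((f.start - 1, f.end, int(f.frame) if f.frame != "." else 0)
                      for f in cds),
        ))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.start + 1, g.end
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\tsesapop\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tsesapop\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={mid};Parent={g.gene_id}\n")
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tsesapop\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                         f"ID={mid}.exon{i};Parent={mid}\n")
            for i, (cs, ce, ph) in enumerate(g.cds, 1):
                fh.write(f"{g.chrom}\tsesapop\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{ph}\t"
                         f"ID={mid}.cds{i};Parent={mid}\n")


def read_fasta(path, check_chroms=None) -> dict[str, str]:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if check_chroms is not None:
        missing = sorted(set(check_chroms) - set(seqs))
        if missing:
            raise ValueError(f"chromosomes absent from FASTA: {', '.join(missing)}")
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


PHENOTYPE_COLUMNS = ["accession", "environment", "trait", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    """Tidy phenotype table: accession, environment, trait, value (e.g. mg/g)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    df = df[PHENOTYPE_COLUMNS].copy()
    if not np.isfinite(df.value.to_numpy(dtype=float)).all():
        raise ValueError("non-finite phenotype values")
    dup = df.duplicated(subset=["accession", "environment", "trait"])
    if dup.any():
        raise ValueError(f"{dup.sum()} duplicate (accession, environment, trait) records")
    df["accession"] = df.accession.astype(str)
    return df


def read_groups(path) -> dict[str, str]:
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"accession", "group"} <= set(df.columns):
        raise ValueError("groups table needs columns: accession, group")
    return dict(zip(df.accession.astype(str), df.group.astype(str)))
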