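"""Shared fixtures: hand-built gene models with known coding effects and a
small simulated panel. Everything is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sesapop.formats import SITE_COLUMNS, GeneModel, GenotypeMatrix

# Plus-strand fixture gene: single 30 bp CDS, codons chosen so every effect
# class is reachable (ACA->AAA Thr->Lys, GCT->GCC Ala->Ala wobble, TGG stop
# gain, terminal TAA stop loss).
PLUS_CDS = "ATGACAGCTCGTAAGGGCTTTCCCTGGTAA"
PLUS_GENE_START = 10

# Minus-strand fixture gene: coding sequence read off the reverse complement.
MINUS_CDS = "ATGCAGGCTAAGTTTGGGCCCTGGTGTTAA"
MINUS_GENE_START = 50

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@pytest.fixture(scope="session")
def fixture_ref_seq() -> str:
    """100 bp chromosome 'ChrT' embedding both fixture genes."""
    seq = list("A" * 100)
    seq[PLUS_GENE_START:PLUS_GENE_START + 30] = PLUS_CDS
    seq[MINUS_GENE_START:MINUS_GENE_START + 30] = revcomp(MINUS_CDS)
    return "".join(seq)


@pytest.fixture(scope="session")
def plus_gene() -> GeneModel:
    return GeneModel("GPLUS", "ChrT", "+", PLUS_GENE_START, PLUS_GENE_START + 30,
                     exons=((PLUS_GENE_START, PLUS_GENE_START + 30),),
                     cds=((PLUS_GENE_START, PLUS_GENE_START + 30, 0),))


@pytest.fixture(scope="session")
def minus_gene() -> GeneModel:
    return GeneModel("GMINUS", "ChrT", "-", MINUS_GENE_START, MINUS_GENE_START + 30,
                     exons=((MINUS_GENE_START, MINUS_GENE_START + 30),),
                     cds=((MINUS_GENE_START, MINUS_GENE_START + 30, 0),))


@pytest.fixture(scope="session")
def spliced_gene() -> GeneModel:
    """Two-exon plus-strand gene with an intron [220, 230) for splice tests."""
    return GeneModel("GSPLICE", "ChrT2", "+", 200, 250,
                     exons=((200, 220), (230, 250)),
                     cds=((200, 220, 0), (230, 250, 1)))


def make_gm(dosage, chrom="Chr1", positions=None, refs=None, alts=None,
            samples=None, depth=None) -> GenotypeMatrix:
    """Handy literal-dosage GenotypeMatrix builder for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    positions = positions if positions is not None else np.arange(m) * 100
    refs = refs if refs is not None else ["A"] * m
    alts = alts if alts is not None else ["G"] * m
    sites = pd.DataFrame(
        [(chrom, int(p), r, a, None) for p, r, a in zip(positions, refs, alts)],
        columns=SITE_COLUMNS)
    samples = samples if samples is not None else [f"s{i:03d}" for i in range(n)]
    return GenotypeMatrix(samples, sites, dosage, depth)


@pytest.fixture(scope="session")
def two_pop_panel():
    """Moderate two-population Balding-Nichols panel with a planted sweep."""
    import sesapop as sp

    cfg = sp.SimConfig(pop_sizes={"MC": 30, "SC": 30}, F=0.05,
                       chrom_lengths={"Chr1": 500_000}, snp_density=0.01,
                       sweeps=(sp.SweepSpec("MC", "Chr1", 200_000, 250_000, 0.9),),
                       seed=7)
    gm, truth = sp.simulate_structured_genotypes(cfg)
    return cfg, gm, truth


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=Chr1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
Chr1\t101\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:20\t0/0:22\t1/1:25
Chr1\t205\t.\tC\tT\t.\tPASS\t.\tGT:DP\t./.:0\t0/1:30\t0/0:18
Chr1\t310\t.\tG\tGA\t.\tPASS\t.\tGT:DP\t0/0:20\t0/1:20\t0/0:20
Chr1\t402\t.\tT\tA\t.\tPASS\t.\tGT:DP\t1/1:9\t1/1:12\t0/1:15
Chr1\t515\t.\tA\tG,T\t.\tPASS\t.\tGT:DP\t0/1:20\t0/2:20\t0/0:20
Chr1\t620\t.\tC\tG\t.\tPASS\t.\tGT:DP\t0/0:21\t0/1:19\t0/1:23
"""


@pytest.fixture()
def toy_vcf_path(tmp_path):
    """Six records: one InDel and one triallelic site -> four biallelic SNPs."""
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p
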