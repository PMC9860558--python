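"""Region classification and coding-effect annotation against hand-built genes."""

import numpy as np
import pytest
from Bio.Seq import Seq

import sesapop as sp
from sesapop.annotate import (annotation_summary, classify_region, coding_effect,
                              ts_tv_ratio)
from sesapop.formats import VariantSite

from conftest import (MINUS_CDS, MINUS_GENE_START, PLUS_CDS, PLUS_GENE_START,
                      revcomp)


def site(chrom, pos, ref, alt):
    return VariantSite(chrom, pos, ref, alt)


class TestClassifyRegion:
    @pytest.mark.parametrize("pos, expected", [
        (5000, "intergenic"),                # 5 kb away from anything
        (PLUS_GENE_START - 500, "upstream"),   # 500 bp 5' of a + gene
        (PLUS_GENE_START + 30 + 10, "downstream"),
        (PLUS_GENE_START + 3, "exonic"),
    ])
    def test_single_gene_classes(self, plus_gene, pos, expected):
        cls, _ = classify_region(site("ChrT", pos, "A", "G"), [plus_gene])
        assert cls == expected

    def test_minus_strand_flanks_swap(self, minus_gene):
        cls, _ = classify_region(site("ChrT", MINUS_GENE_START - 100, "A", "G"),
                                 [minus_gene])
        assert cls == "downstream"
        cls, _ = classify_region(
            site("ChrT", MINUS_GENE_START + 30 + 100, "A", "G"), [minus_gene])
        assert cls == "upstream"

    @pytest.mark.parametrize("pos, expected", [
        (220, "splicing"), (221, "splicing"),   # within 2 bp of exon1 end
        (228, "splicing"), (229, "splicing"),   # within 2 bp of exon2 start
        (224, "intronic"),                      # mid-intron
        (210, "exonic"),
    ])
    def test_splice_window_boundaries(self, spliced_gene, pos, expected):
        """1-2 bp into the intron is splicing; deeper is intronic."""
        cls, _ = classify_region(site("ChrT2", pos, "A", "G"), [spliced_gene])
        assert cls == expected

    def test_precedence_exonic_over_flank(self, plus_gene, minus_gene):
        # position inside GPLUS exon also lies downstream of GMINUS flank? No
        # overlap here, so craft precedence via all_overlaps on a flank case.
        hits = classify_region(site("ChrT", PLUS_GENE_START + 3, "A", "G"),
                               [plus_gene, minus_gene], all_overlaps=True)
        assert ("exonic", "GPLUS") in hits


class TestCodingEffect:
    def test_thr_to_lys_second_position(self, plus_gene, fixture_ref_seq):
        """ACA -> AAA at the second codon position is Thr->Lys."""
        pos = PLUS_GENE_START + 4
        eff, aa = coding_effect(site("ChrT", pos, "C", "A"), plus_gene,
                                fixture_ref_seq)
        assert eff == "nonsynonymous" and aa == "Thr->Lys"

    def test_third_position_wobble_synonymous(self, plus_gene, fixture_ref_seq):
        pos = PLUS_GENE_START + 8   # GCT -> GCC
        eff, aa = coding_effect(site("ChrT", pos, "T", "C"), plus_gene,
                                fixture_ref_seq)
        assert eff == "synonymous" and aa == "Ala->Ala"

    def test_stop_gain_and_loss(self, plus_gene, fixture_ref_seq):
        eff, aa = coding_effect(site("ChrT", PLUS_GENE_START + 26, "G", "A"),
                                plus_gene, fixture_ref_seq)   # TGG -> TGA
        assert eff == "stop_gain" and aa == "Trp->Ter"
        eff, _ = coding_effect(site("ChrT", PLUS_GENE_START + 27, "T", "C"),
                               plus_gene, fixture_ref_seq)    # TAA -> CAA
        assert eff == "stop_loss"

    def test_minus_strand_hand_computed(self, minus_gene, fixture_ref_seq):
        """Genomic T->A whose coding codon is CAG->CTG (Gln->Leu)."""
        cpos = 4                               # middle of codon 2 (CAG)
        gpos = MINUS_GENE_START + (29 - cpos)
        assert fixture_ref_seq[gpos] == "T"    # complement of coding A
        eff, aa = coding_effect(site("ChrT", gpos, "T", "A"), minus_gene,
                                fixture_ref_seq)
        assert eff == "nonsynonymous" and aa == "Gln->Leu"

    def test_ref_mismatch_raises(self, plus_gene, fixture_ref_seq):
        with pytest.raises(ValueError, match="REF mismatch"):
            coding_effect(site("ChrT", PLUS_GENE_START + 4, "G", "A"),
                          plus_gene, fixture_ref_seq)

    @pytest.mark.parametrize("gene_name, cds", [("plus", PLUS_CDS),
                                                ("minus", MINUS_CDS)])
    def test_whole_protein_diff_oracle(self, gene_name, cds, plus_gene,
                                       minus_gene, fixture_ref_seq):
        """Exhaustive agreement with a brute-force oracle that substitutes the
        allele in the full CDS, translates the whole protein, and diffs it."""
        gene = plus_gene if gene_name == "plus" else minus_gene
        for cpos in range(len(cds)):
            for alt_c in "ACGT":
                if alt_c == cds[cpos]:
                    continue
                if gene.strand == "+":
                    gpos = gene.start + cpos
                    g_ref, g_alt = cds[cpos], alt_c
                else:
                    gpos = gene.start + (len(cds) - 1 - cpos)
                    g_ref, g_alt = revcomp(cds[cpos]), revcomp(alt_c)
                eff, _ = coding_effect(site("ChrT", gpos, g_ref, g_alt), gene,
                                       fixture_ref_seq)
                prot_ref = str(Seq(cds).translate())
                mutated = cds[:cpos] + alt_c + cds[cpos + 1:]
                prot_alt = str(Seq(mutated).translate())
                if prot_ref == prot_alt:
                    expected = "synonymous"
                elif "*" in prot_alt and prot_alt.count("*") > prot_ref.count("*"):
                    expected = "stop_gain"
                elif prot_alt.count("*") < prot_ref.count("*"):
                    expected = "stop_loss"
                else:
                    expected = "nonsynonymous"
                assert eff == expected, (gene_name, cpos, alt_c)

    def test_strand_symmetry(self, plus_gene, fixture_ref_seq):
        """Annotating the reverse-complemented gene yields identical effects."""
        L = len(fixture_ref_seq)
        rc_seq = revcomp(fixture_ref_seq)
        rc_gene = sp.GeneModel("GRC", "ChrT", "-",
                               L - (plus_gene.end), L - plus_gene.start,
                               exons=((L - plus_gene.end, L - plus_gene.start),),
                               cds=((L - plus_gene.end, L - plus_gene.start, 0),))
        for off, ref, alt in [(4, "C", "A"), (8, "T", "C"), (26, "G", "A")]:
            gpos = PLUS_GENE_START + off
            fwd, aa_f = coding_effect(site("ChrT", gpos, ref, alt), plus_gene,
                                      fixture_ref_seq)
            rpos = L - 1 - gpos
            rev, aa_r = coding_effect(
                site("ChrT", rpos, revcomp(ref), revcomp(alt)), rc_gene, rc_seq)
            assert (fwd, aa_f) == (rev, aa_r)


class TestSummaries:
    def test_ts_tv_by_definition(self):
        sites = [site("c", i * 10, r, a) for i, (r, a) in enumerate(
            [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")])]
        assert ts_tv_ratio(sites) == 2.0
        with pytest.warns(UserWarning):
            assert ts_tv_ratio([site("c", 0, "A", "G")]) == float("inf")
        assert ts_tv_ratio([site("c", 0, "A", "C"), site("c", 9, "A", "T")]) == 0.0

    def test_proportions_sum_to_one_and_ratio(self, plus_gene, fixture_ref_seq):
        anns = ([sp.SiteAnnotation(site("c", i, "A", "G"), "intergenic")
                 for i in range(10)]
                + [sp.SiteAnnotation(site("c", 100 + i, "A", "G"), "exonic",
                                     "G", "nonsynonymous", "Thr->Lys")
                   for i in range(2)])
        s = annotation_summary(anns)
        assert abs(sum(s["region_proportions"].values()) - 1) < 1e-12
        assert s["region_proportions"]["intergenic"] == pytest.approx(10 / 12)
        assert s["ns_s_ratio"] == float("inf") or s["ns_s_ratio"] > 0

    def test_ns_s_ratio_balanced(self):
        anns = ([sp.SiteAnnotation(site("c", i, "A", "G"), "exonic", "G",
                                   "synonymous", "Ala->Ala") for i in range(3)]
                + [sp.SiteAnnotation(site("c", 50 + i, "A", "G"), "exonic", "G",
                                     "nonsynonymous", "Thr->Lys") for i in range(3)])
        assert annotation_summary(anns)["ns_s_ratio"] == 1.0

    def test_empty_input_no_crash(self):
        s = annotation_summary([])
        assert s["n"] == 0 and s["region_proportions"] == {}
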