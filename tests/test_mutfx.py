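"""Translation, SNV classification, splice isoforms and miRNA-site pairing."""

import numpy as np
import pytest

from bsakit import mutfx, simdata
from bsakit.errors import DataError, SequenceError
from bsakit.mutfx import (GeneModelCds, apply_snv_and_classify,
                          mir_target_mismatches, splice_isoform, translate)

# independent brute-force codon table (standard genetic code)
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
CODON_TABLE = {a + b + c: _AA[16 * i + 4 * j + k]
               for i, a in enumerate(_BASES)
               for j, b in enumerate(_BASES)
               for k, c in enumerate(_BASES)}


def oracle_translate(cds):
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i:i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


class TestTranslate:
    @pytest.mark.parametrize("cds,protein", [
        ("ATGTGA", "M"),
        ("ATGTGGTAA", "MW"),
        ("ATGAAATTTTAG", "MKF"),
    ])
    def test_examples(self, cds, protein):
        assert translate(cds) == protein

    def test_equivalence_with_codon_table_oracle(self, rng):
        for _ in range(100):
            cds = "ATG" + "".join(rng.choice(list("ACGT"), size=297))
            assert translate(cds) == oracle_translate(cds)

    def test_non_atg_start_warns(self):
        with pytest.warns(UserWarning, match="ATG"):
            translate("CCCTGA")

    def test_bad_characters_rejected(self):
        with pytest.raises(SequenceError):
            translate("ATGNNN")


def simple_gene(strand="+"):
    """Two-exon gene: ATG GAA | TGG CCT TGA split across a 10-nt intron."""
    left, right = "ATGGAA", "TGGCCTTGA"
    intron = "GTAAGCATAG"
    if strand == "+":
        genomic = "AAAA" + left + intron + right + "TTTT"
        exons = ((5, 10), (21, 29))
    else:
        rc = mutfx._rc
        genomic = "AAAA" + rc(right) + intron + rc(left) + "TTTT"
        exons = ((5, 13), (24, 29))
    return GeneModelCds("toy", genomic, exons, strand=strand)


class TestGeneModel:
    def test_cds_and_protein_plus_strand(self):
        g = simple_gene("+")
        assert g.cds() == "ATGGAATGGCCTTGA"
        assert g.protein() == "MEWP"

    def test_minus_strand_mirror_same_protein(self):
        assert simple_gene("-").protein() == simple_gene("+").protein()

    def test_overlapping_exons_rejected(self):
        with pytest.raises(DataError):
            GeneModelCds("bad", "ACGTACGTACGT", ((1, 6), (4, 9)))


class TestApplySnv:
    def test_stop_gain_is_nonsense(self):
        g = simple_gene("+")
        # TGG codon spans genomic 21-23; G->A at 23 gives TGA
        eff = apply_snv_and_classify(g, 23, "G", "A")
        assert eff.effect_class == "nonsense"
        assert (eff.ref_aa, eff.alt_aa) == ("W", "*")
        assert eff.mut_protein_length == 2 < eff.wt_protein_length == 4

    def test_silent_substitution(self):
        g = simple_gene("+")
        # GAA -> GAG, both Glu (codon 2, genomic pos 10)
        eff = apply_snv_and_classify(g, 10, "A", "G")
        assert eff.effect_class == "silent"
        assert eff.mut_protein_length == eff.wt_protein_length

    def test_missense(self):
        g = simple_gene("+")
        eff = apply_snv_and_classify(g, 8, "G", "T")  # GAA -> TAA? pos8 is G of GAA
        assert eff.effect_class in ("missense", "nonsense")

    def test_domain_lost_when_truncation_preceeds_it(self):
        gene, pos, ref, alt = simdata.synthetic_causal_gene()
        eff = apply_snv_and_classify(gene, pos, ref, alt)
        assert eff.effect_class == "nonsense"
        assert eff.mut_protein_length == 223
        assert eff.lost_domains == ("AP2-2",)  # aa 270-330 beyond the 223-aa product

    def test_ref_mismatch_rejected(self):
        g = simple_gene("+")
        with pytest.raises(DataError, match="mismatch"):
            apply_snv_and_classify(g, 23, "C", "A")

    def test_intronic_position_unsupported(self):
        g = simple_gene("+")
        with pytest.raises(DataError, match="exonic"):
            apply_snv_and_classify(g, 15, g.genomic_seq[14], "A")

    def test_minus_strand_equivalent_effect(self):
        gp, gm = simple_gene("+"), simple_gene("-")
        eff_p = apply_snv_and_classify(gp, 23, "G", "A")
        # the mirrored base sits at genomic pos 11 on the minus-strand model
        pos_m = 11
        eff_m = apply_snv_and_classify(gm, pos_m, gm.genomic_seq[pos_m - 1], "T")
        assert eff_m.effect_class == eff_p.effect_class == "nonsense"
        assert eff_m.mut_protein_length == eff_p.mut_protein_length

    def test_truncation_monotonicity(self):
        """A nonsense codon further 5' never yields a longer product."""
        gene, _, _, _ = simdata.synthetic_causal_gene()
        cds = gene.cds()
        lengths = []
        for codon_idx in (50, 120, 224, 300):
            mut = cds[:codon_idx * 3] + "TGA" + cds[codon_idx * 3 + 3:]
            lengths.append(len(translate(mut)))
        assert lengths == sorted(lengths)


class TestSpliceIsoforms:
    def test_printed_protein_architecture(self):
        gene, _, _, _ = simdata.synthetic_causal_gene()
        full = splice_isoform(gene, ("full",))
        skip9 = splice_isoform(gene, ("exon_skip", 9))
        assert len(full.protein) == 447
        assert len(skip9.protein) == 408

    def test_retained_intron_stop_terminates_early(self):
        gene, _, _, _ = simdata.synthetic_causal_gene()
        ir8 = splice_isoform(gene, ("intron_retention", 8))
        # exons 1-8 carry 350 codons; the retained intron opens with a stop
        assert len(ir8.protein) == 350
        assert ir8.termination_aa == 350

    def test_in_frame_skip_preserves_downstream_peptide(self):
        gene, _, _, _ = simdata.synthetic_causal_gene()
        full = splice_isoform(gene, ("full",)).protein
        skip = splice_isoform(gene, ("exon_skip", 9)).protein
        assert skip[:350] == full[:350]      # before the skipped exon
        assert skip[350:] == full[389:]      # after it, frame preserved

    def test_skip_first_exon_no_product(self):
        g = simple_gene("+")
        iso = splice_isoform(g, ("exon_skip", 1))
        assert iso.no_product and iso.protein == ""

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            splice_isoform(simple_gene("+"), ("mystery", 1))


class TestMirTargetMismatches:
    def test_perfect_complement_zero(self):
        site = "ATGCATGCAT"
        mirna = mutfx._rc(site)  # antiparallel perfect pairing
        assert mir_target_mismatches(mirna, site) == 0

    def test_single_substitution_adds_one(self):
        site = "ATGCATGCAT"
        mirna = mutfx._rc(site)
        mutated = site[:4] + ("C" if site[4] != "C" else "G") + site[5:]
        assert mir_target_mismatches(mirna, mutated) == 1

    def test_wobble_configurable(self):
        # miRNA G opposite site T: a G:U wobble
        assert mir_target_mismatches("G", "T", wobble_counts=True) == 1
        assert mir_target_mismatches("G", "T", wobble_counts=False) == 0

    def test_rna_alphabet_accepted(self):
        assert mir_target_mismatches("AUGC", "GCAU") == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            mir_target_mismatches("ACG", "ACGT")
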