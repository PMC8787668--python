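"""TSS-distance assignment, target calling, DEG intersection and k-mer ranking."""

import collections

import numpy as np
import pandas as pd
import pytest

from bsakit import daptargets, simdata
from bsakit.errors import DataError, SequenceError
from bsakit.daptargets import (assign_peaks, dinucleotide_shuffle, intersect_degs,
                               kmer_enrichment, peak_anchor, putative_targets,
                               signed_tss_distance)


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestSignedDistance:
    def test_anchor_at_tss_zero(self):
        assert signed_tss_distance(1_000, 1_000, "+") == 0

    def test_minus_strand_higher_coordinate_is_upstream(self):
        assert signed_tss_distance(1_100, 1_000, "-") == -100

    def test_strand_mirror_symmetry(self):
        # reflect coordinates around L and flip strand: distance preserved
        L = 10_000
        d_plus = signed_tss_distance(4_000, 4_500, "+")
        d_mirror = signed_tss_distance(L - 4_000, L - 4_500, "-")
        assert d_plus == d_mirror

    def test_bad_strand_rejected(self):
        with pytest.raises(DataError):
            signed_tss_distance(1, 1, "*")


class TestAssignPeaks:
    GENES = gene_frame([
        ("geneA", "1A", 50_000, 53_000, "+", 50_000),
        ("geneB", "1A", 90_000, 94_000, "-", 94_000),
    ])

    def _assign_one(self, start, end):
        peaks = peak_frame([("1A", start, end, "p1")])
        return assign_peaks(peaks, self.GENES).iloc[0]

    def test_upstream_1060_is_putative_target(self):
        # anchor 1,060 bp upstream of geneA's TSS
        anchor = 50_000 - 1_060
        a = self._assign_one(anchor - 51, anchor + 50)
        assert a.gene_id == "geneA"
        assert a.distance == -1_060
        assert a.is_putative_target and a.in_genic_window

    def test_minus_2500_genic_but_not_target(self):
        anchor = 50_000 - 2_500
        a = self._assign_one(anchor - 51, anchor + 50)
        assert a.distance == -2_500
        assert a.in_genic_window and not a.is_putative_target

    def test_plus_501_excluded_from_target_window(self):
        anchor = 50_000 + 501
        a = self._assign_one(anchor - 51, anchor + 50)
        assert a.distance == 501
        assert not a.is_putative_target

    def test_minus_strand_gene_direction(self):
        # anchor 500 bp beyond geneB's TSS coordinate = 500 bp upstream on - strand
        anchor = 94_000 + 500
        a = self._assign_one(anchor - 51, anchor + 50)
        assert a.gene_id == "geneB" and a.distance == -500

    def test_translation_invariance(self):
        peaks = peak_frame([("1A", 48_000, 48_100, "p1"), ("1A", 95_000, 95_100, "p2")])
        base = assign_peaks(peaks, self.GENES)
        shift = 7_777
        peaks2 = peaks.assign(start=peaks.start + shift, end=peaks.end + shift)
        genes2 = self.GENES.assign(start=self.GENES.start + shift,
                                   end=self.GENES.end + shift,
                                   tss=self.GENES.tss + shift)
        moved = assign_peaks(peaks2, genes2)
        pd.testing.assert_frame_equal(base, moved)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(DataError):
            assign_peaks(peak_frame([("1A", 0, 100, "p")]), self.GENES.iloc[0:0])

    def test_anchor_is_midpoint(self):
        assert peak_anchor(100, 200) == 151
        with pytest.raises(DataError):
            peak_anchor(200, 200)


class TestIntersectDegs:
    def _degs(self, down, up, null):
        idx = down + up + null
        return pd.DataFrame({
            "is_deg": [True] * (len(down) + len(up)) + [False] * len(null),
            "direction": ["down"] * len(down) + ["up"] * len(up) + ["down"] * len(null),
        }, index=idx)

    def test_disjoint_sets_empty(self):
        degs = self._degs(["g1"], ["g2"], [])
        assert intersect_degs({"g9"}, degs) == (set(), set())

    def test_constructed_truth_recovered(self):
        targets = {f"t{i}" for i in range(20)}
        degs = self._degs([f"t{i}" for i in range(5)], ["t19"], ["t10", "x1"])
        down, up = intersect_degs(targets, degs)
        assert down == {f"t{i}" for i in range(5)}
        assert up == {"t19"}

    def test_partition_sums_to_intersection(self):
        degs = self._degs(["a", "b"], ["c"], ["d"])
        targets = {"a", "c", "d", "e"}
        down, up = intersect_degs(targets, degs)
        de_genes = set(degs[degs.is_deg].index)
        assert len(down) + len(up) == len(targets & de_genes)


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 120)))
            shuf = dinucleotide_shuffle(seq, rng)
            orig = collections.Counter(a + b for a, b in zip(seq, seq[1:]))
            new = collections.Counter(a + b for a, b in zip(shuf, shuf[1:]))
            assert orig == new
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_actually_shuffles(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert any(dinucleotide_shuffle(seq, rng) != seq for _ in range(5))


class TestKmerEnrichment:
    def test_k1_on_homopolymer(self):
        hits = kmer_enrichment(["AAAA"], k=1, n_shuffles=2, seed=0)
        assert len(hits) == 1
        assert hits.iloc[0].kmer == "A" and hits.iloc[0].fg_count == 4

    def test_implanted_motif_ranked_first(self):
        genes = simdata.simulate_gene_models((("1A", 3_000_000),), 50, seed=1)
        _, seqs = simdata.simulate_peaks_and_sequences(
            genes, n_target=0, n_peaks=150, motif="CTTGC",
            implant_fraction=1.0, seed=1)
        hits = kmer_enrichment(list(seqs.values()), k=5, seed=1)
        assert hits.iloc[0].kmer == "CTTGC"  # canonical: CTTGC < GCAAG

    def test_score_decreases_with_implant_fraction(self):
        genes = simdata.simulate_gene_models((("1A", 3_000_000),), 50, seed=2)
        scores = []
        for frac in (1.0, 0.75, 0.5, 0.25, 0.1):
            _, seqs = simdata.simulate_peaks_and_sequences(
                genes, n_target=0, n_peaks=150, motif="CTTGC",
                implant_fraction=frac, seed=2)
            hits = kmer_enrichment(list(seqs.values()), k=5, seed=2)
            scores.append(float(hits.set_index("kmer").loc["CTTGC", "score"]))
        assert scores == sorted(scores, reverse=True)

    def test_short_sequence_rejected(self):
        with pytest.raises(SequenceError):
            kmer_enrichment(["ACG"], k=5)

    def test_random_sequences_top_score_modest(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(80)]
        null_top = kmer_enrichment(seqs, k=5, seed=3).iloc[0].score
        genes = simdata.simulate_gene_models((("1A", 3_000_000),), 50, seed=3)
        _, implanted = simdata.simulate_peaks_and_sequences(
            genes, n_target=0, n_peaks=80, motif="CTTGC", implant_fraction=1.0, seed=3)
        implant_top = kmer_enrichment(list(implanted.values()), k=5, seed=3).iloc[0].score
        assert implant_top > null_top


class TestEndToEndTargetTruth:
    def test_target_genes_recovered(self):
        genes = simdata.simulate_gene_models((("1A", 25_000_000), ("2B", 25_000_000)),
                                             60, seed=9)
        peaks, _ = simdata.simulate_peaks_and_sequences(genes, n_target=20,
                                                        n_peaks=60, seed=9)
        assign = assign_peaks(peaks, genes)
        called = putative_targets(assign)
        truth = set(peaks.loc[peaks.is_target_truth, "target_gene_truth"])
        assert truth <= called
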