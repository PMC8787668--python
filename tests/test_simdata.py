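"""Synthetic cross, bulks, read depths, counts and peaks behave as designed."""

import numpy as np
import pandas as pd
import pytest

from bsakit import simdata
from bsakit.errors import ConfigurationError, SamplingError


def _cfg(**kw):
    base = dict(chromosomes=(("5A", 50_000_000),), causal_locus=("5A", 40_000_000),
                n_f2=400, seed=1)
    base.update(kw)
    return simdata.SimConfig(**base)


class TestF2Population:
    def test_genotype_frequencies_one_to_two_to_one(self):
        cfg = _cfg(n_f2=10_000)
        pop = simdata.simulate_f2_population(cfg)
        dos = np.array([ind.dosage_at("5A", 12_345_678)[0] for ind in pop])
        n = len(dos)
        for count, p in ((np.sum(dos == 2), 0.25), (np.sum(dos == 1), 0.5),
                         (np.sum(dos == 0), 0.25)):
            se = np.sqrt(p * (1 - p) * n)
            assert abs(count - p * n) < 3 * se

    def test_phenotype_ratio_three_to_one(self):
        from bsakit.linkage import chi_square_segregation
        pop = simdata.simulate_f2_population(_cfg(n_f2=10_000))
        n_dom = sum(p.phenotype == simdata.SPELTOID for p in pop)
        res = chi_square_segregation(n_dom, len(pop) - n_dom, ratio=(3, 1))
        assert res.p_value > 0.05

    def test_no_recombination_means_constant_genotype(self):
        pop = simdata.simulate_f2_population(_cfg(map_function=0.0, n_f2=50, bulk_size=10))
        pos = np.array([1, 10_000_000, 25_000_000, 49_999_999])
        for ind in pop:
            assert len(set(ind.dosage_at("5A", pos))) == 1

    def test_phenotype_matches_causal_genotype(self):
        pop = simdata.simulate_f2_population(_cfg(n_f2=500))
        for ind in pop:
            carrier = ind.dosage_at("5A", 40_000_000)[0] >= 1
            assert (ind.phenotype == simdata.SPELTOID) == carrier

    def test_genotype_track_symbols(self):
        pop = simdata.simulate_f2_population(_cfg(n_f2=5, bulk_size=2))
        track = pop[0].genotype_track({"5A": np.array([1_000_000, 2_000_000])})
        assert set(g for _, g in track["5A"]) <= {"AA", "Aa", "aa"}

    @pytest.mark.parametrize("kw", [
        dict(n_f2=0), dict(chromosomes=(("5A", 0),), causal_locus=("5A", 1)),
        dict(causal_locus=("chrX", 1)), dict(bulk_size=300),
        dict(depth_lambda=0.0), dict(misclassification_rate=1.0),
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            _cfg(**kw)


class TestBulks:
    def test_insufficient_phenotype_raises_named_deficit(self, small_population):
        spelt = [p for p in small_population if p.phenotype == simdata.SPELTOID][:100]
        normal = [p for p in small_population if p.phenotype == simdata.NORMAL][:40]
        with pytest.raises(SamplingError, match="normal"):
            simdata.build_bulks(spelt + normal, 50, seed=0)

    def test_bulks_pure_disjoint_and_sized(self, small_population, small_bulks):
        by_id = {p.id: p for p in small_population}
        assert len(small_bulks.mutant_bulk) == len(small_bulks.wt_bulk) == 50
        assert not set(small_bulks.mutant_bulk) & set(small_bulks.wt_bulk)
        assert all(by_id[i].phenotype == simdata.SPELTOID for i in small_bulks.mutant_bulk)
        assert all(by_id[i].phenotype == simdata.NORMAL for i in small_bulks.wt_bulk)

    def test_same_seed_same_membership(self, small_population):
        b1 = simdata.build_bulks(small_population, 50, seed=42)
        b2 = simdata.build_bulks(small_population, 50, seed=42)
        assert b1 == b2


class TestBulkReadcounts:
    def test_allele_frequencies_at_linked_and_unlinked_loci(self):
        """Causal locus: mutant bulk f = 2/3 (AA:Aa 1:2 among dominants), wt bulk 0.

        An unlinked locus segregates independently: f = 1/2 in either bulk.
        Averaged over seeded replicates of the whole design.
        """
        cfg = simdata.SimConfig(
            chromosomes=(("5A", 50_000_000), ("1A", 50_000_000)),
            causal_locus=("5A", 40_000_000), n_f2=300, seed=0)
        pos = {"5A": np.array([40_000_000]), "1A": np.array([25_000_000])}
        f_mut, f_wt, f_unl = [], [], []
        for seed in range(40):
            pop = simdata.simulate_f2_population(
                simdata.SimConfig(**{**cfg.__dict__, "seed": seed}))
            bulks = simdata.build_bulks(pop, 50, seed=seed)
            t = simdata.simulate_bulk_readcounts(bulks, pop, pos, 100, seed=seed)
            causal = t[t.chrom == "5A"].iloc[0]
            unlinked = t[t.chrom == "1A"].iloc[0]
            f_mut.append(causal.bulk_mut_alt / causal.bulk_mut_dp)
            f_wt.append(causal.bulk_wt_alt / causal.bulk_wt_dp)
            f_unl.append(unlinked.bulk_mut_alt / unlinked.bulk_mut_dp)
        assert abs(np.mean(f_mut) - 2 / 3) < 0.03
        assert np.mean(f_wt) < 0.02
        assert abs(np.mean(f_unl) - 0.5) < 0.05

    def test_parents_fixed_opposite_homozygotes(self, one_chrom_config,
                                                small_population, small_bulks):
        pos = simdata.draw_snp_positions(one_chrom_config)
        t = simdata.simulate_bulk_readcounts(small_bulks, small_population, pos, 50, seed=3)
        assert (t.pA_ref == 0).all() and (t.pB_alt == 0).all()
        assert ((t.bulk_mut_alt <= t.bulk_mut_dp) & (t.bulk_wt_alt <= t.bulk_wt_dp)).all()

    def test_byte_identical_under_fixed_seed(self, one_chrom_config,
                                             small_population, small_bulks):
        pos = simdata.draw_snp_positions(one_chrom_config)
        a = simdata.simulate_bulk_readcounts(small_bulks, small_population, pos, 50, seed=9)
        b = simdata.simulate_bulk_readcounts(small_bulks, small_population, pos, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_causal_position_always_a_snp(self, one_chrom_config):
        pos = simdata.draw_snp_positions(one_chrom_config)
        assert 40_000_000 in pos["5A"]


class TestExpressionCounts:
    def test_de_fraction_zero_all_null(self):
        _, _, truth = simdata.simulate_expression_counts(100, 3, 0.0, 2.0, 0.01, seed=0)
        assert not truth.is_de.any()

    def test_fold_one_groups_exchangeable(self):
        counts, _, truth = simdata.simulate_expression_counts(
            2_000, 3, 0.5, 1.0, 0.01, seed=0)
        a = counts[["A1", "A2", "A3"]].to_numpy().mean()
        b = counts[["B1", "B2", "B3"]].to_numpy().mean()
        assert abs(np.log2(b / a)) < 0.05

    def test_low_dispersion_approaches_poisson(self):
        counts, _, _ = simdata.simulate_expression_counts(
            3_000, 10, 0.0, 2.0, 1e-9, seed=0, mean_log=4.0, mean_sigma=0.0)
        x = counts.to_numpy()
        ratio = x.var(axis=1, ddof=1) / x.mean(axis=1)
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_invalid_fold_rejected(self):
        with pytest.raises(ConfigurationError):
            simdata.simulate_expression_counts(10, 3, 0.1, 0.0, 0.1, seed=0)


@pytest.fixture(scope="module")
def genes():
    return simdata.simulate_gene_models((("1A", 20_000_000),), 40, seed=5)


class TestPeaks:

    def test_no_targets_no_implant_beyond_chance(self, genes):
        peaks, seqs = simdata.simulate_peaks_and_sequences(
            genes, n_target=0, n_peaks=50, seed=1)
        hits = sum("CTTGC" in s or "GCAAG" in s for s in seqs.values())
        assert hits <= 0.6 * len(seqs)  # random 100-mers only (p ~ 0.3/seq)

    def test_target_peaks_fall_in_target_window(self, genes):
        from bsakit import daptargets
        peaks, _ = simdata.simulate_peaks_and_sequences(
            genes, n_target=20, n_peaks=40, seed=2)
        assign = daptargets.assign_peaks(peaks, genes)
        tgt = peaks[peaks.is_target_truth].merge(assign, left_on="name", right_on="peak")
        assert tgt.is_putative_target.all()

    def test_implanted_motif_present_in_targets(self, genes):
        _, seqs = simdata.simulate_peaks_and_sequences(
            genes, n_target=10, n_peaks=20, motif="CTTGC", seed=3)
        peaks, _ = simdata.simulate_peaks_and_sequences(
            genes, n_target=10, n_peaks=20, motif="CTTGC", seed=3)
        for name in [f"peak{i:05d}" for i in range(10)]:
            assert "CTTGC" in seqs[name]

    def test_window_wider_than_chromosome_rejected(self):
        tiny = simdata.simulate_gene_models((("1A", 2_000_000),), 5, seed=0)
        with pytest.raises(ConfigurationError):
            simdata.simulate_peaks_and_sequences(
                tiny, n_target=1, n_peaks=2, window=(-3_000_000, 500),
                chrom_lengths={"1A": 2_000_000}, seed=0)


class TestCategoryTable:
    def test_exact_category_totals(self):
        from bsakit import snpfilter
        t = simdata.table_from_category_counts(120, 40, 60, seed=2)
        kept, acc = snpfilter.run_filters(t)
        assert (acc.total, acc.removed_low_depth, acc.removed_monomorphic,
                acc.retained) == (220, 120, 40, 60)


class TestSyntheticGene:
    def test_architecture(self):
        gene, pos, ref, alt = simdata.synthetic_causal_gene()
        assert len(gene.cds()) == 1_344
        assert len(gene.protein()) == 447
        assert gene.genomic_seq[pos - 1] == ref == "G"

    def test_amplicon_pair_differs_at_one_base(self):
        wt, mut = simdata.make_amplicon_pair()
        assert len(wt) == len(mut) == 395
        assert sum(a != b for a, b in zip(wt, mut)) == 1
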