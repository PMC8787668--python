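"""Call DEGs and intersect them with DAP-seq putative target genes.

Expression counts are simulated with implanted two-to-fourfold effects and
called with the twofold + FDR < 0.05 rule (Welch on log2(FPKM+1), BH
adjustment). Binding peaks are assigned to the nearest TSS; peaks within
-2 kb/+500 bp define putative direct targets; the intersection with DEGs
splits into down- and upregulated bound genes. A 5-mer enrichment scan over
a dinucleotide-shuffled background recovers the implanted CTTGC core motif.
"""

from bsakit import daptargets, expression, simdata

chroms = tuple((f"{n}A", 30_000_000) for n in range(1, 4))
genes = simdata.simulate_gene_models(chroms, 300, seed=4)
counts, lengths, truth = simdata.simulate_expression_counts(
    300, 3, de_fraction=0.1, fold=4.0, dispersion=0.01, seed=4)
counts.index = genes.gene_id
lengths.index = genes.gene_id
degs = expression.call_degs(counts, lengths,
                            {"WT": ["A1", "A2", "A3"], "mut": ["B1", "B2", "B3"]})
print(f"{int(degs.is_deg.sum())} DEGs of {len(degs)} genes "
      f"(truth: {int(truth.is_de.sum())} simulated)")

peaks, seqs = simdata.simulate_peaks_and_sequences(
    genes, n_target=30, n_peaks=120, motif="CTTGC", seed=4)
assign = daptargets.assign_peaks(peaks, genes)
targets = daptargets.putative_targets(assign)
print(f"{int(assign.in_genic_window.sum())} of {len(assign)} peaks in the "
      f"-10 kb/+5 kb genic window; {len(targets)} putative target genes "
      "(-2 kb/+500 bp of a TSS)")

down, up = daptargets.intersect_degs(targets, degs)
print(f"bound targets with expression changes: {len(down)} down, {len(up)} up")

hits = daptargets.kmer_enrichment([seqs[n] for n in sorted(seqs)], k=5, seed=4)
top = hits.iloc[0]
print(f"top enriched 5-mer: {top.kmer} (score {top.score:.2f}) "
      "- the implanted binding motif")

qpcr = expression.delta_delta_ct([22.1, 22.0, 22.2], [18.0, 18.1, 18.0],
                                 [20.0, 20.1, 19.9], [18.0, 18.0, 18.1])
print(f"qPCR 2^-ddCT relative expression: {qpcr.relative_expression:.2f} "
      f"+/- {qpcr.sd:.2f} (mutant vs WT calibrator)")
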