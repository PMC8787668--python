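"""Predict the coding effect of the causal SNV and the splice-isoform products.

The synthetic gene mirrors the mapped locus's architecture: a 1,344-nt CDS
over 10 exons encoding 447 aa with two AP2-like domains. The G-to-A SNV in
exon 5 converts codon 224 (TGG, Trp) into a stop, truncating the protein to
223 aa and losing the second domain. Declared splice events: exon-9 skip
(in frame) and intron-8 retention (carries a stop).
"""

from bsakit import mutfx, simdata

gene, snv_pos, ref, alt = simdata.synthetic_causal_gene()
eff = mutfx.apply_snv_and_classify(gene, snv_pos, ref, alt)
print(f"SNV {ref}>{alt} at genomic position {snv_pos}: {eff.effect_class}")
print(f"codon {eff.codon_index}: {eff.ref_aa} -> {eff.alt_aa}")
print(f"protein {eff.wt_protein_length} aa -> {eff.mut_protein_length} aa; "
      f"domains lost: {', '.join(eff.lost_domains)}")

for event, name in ((("full",), "T1"), (("exon_skip", 9), "T2"),
                    (("intron_retention", 8), "T3")):
    iso = mutfx.splice_isoform(gene, event, name)
    print(f"{name} ({'_'.join(map(str, event))}): transcript {len(iso.transcript)} nt, "
          f"protein {len(iso.protein)} aa")
print("T2 skips an in-frame 117-nt exon (447-39=408 aa); T3 terminates inside "
      "the retained intron")

mirna = "TGGCATGCATCAGGATTCCCA"
site = mutfx._rc(mirna)  # a perfectly complementary target site
print(f"miRNA target-site mismatches (perfect site): "
      f"{mutfx.mir_target_mismatches(mirna, site)}")
mut_site = site[:10] + ("A" if site[10] != "A" else "G") + site[11:]
print(f"after one target-site SNP: {mutfx.mir_target_mismatches(mirna, mut_site)} "
      "(reduced cleavage efficiency)")
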