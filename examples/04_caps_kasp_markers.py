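"""Design CAPS and KASP diagnostic assays for a causal SNP.

The G-to-A mutation creates a DdeI restriction site (CTNAG) present only in
the mutant amplicon: the WT allele stays a single uncut band, the mutant
digests into two fragments, and a heterozygote shows all three bands. The
KASP assay puts the SNP at the 3' end of two tailed allele-specific primers.
"""

from bsakit import markerdesign, simdata

amp_wt, amp_mut = simdata.make_amplicon_pair(seed=0, length=395)
assays = markerdesign.design_caps(amp_wt, amp_mut)
for a in assays:
    print(f"{a.enzyme.name} ({a.enzyme.recognition}): "
          f"WT bands {list(a.bands_wt)}, mutant bands {list(a.bands_mut)}, "
          f"heterozygote bands {list(a.bands_het)}")
print("three heterozygote bands = the diagnostic co-dominant pattern on a gel")

centre = len(amp_wt) // 2
kasp = markerdesign.design_kasp(amp_wt[:centre + 1], amp_wt[centre + 1],
                                amp_mut[centre + 1], amp_wt[centre + 2:])
print(f"FAM primer: {kasp.allele1_forward}")
print(f"HEX primer: {kasp.allele2_forward}")
print(f"common rev: {kasp.common_reverse}")
print("the two forwards differ only at their 3'-terminal (SNP) base")
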