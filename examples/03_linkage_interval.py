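"""Delimit the candidate interval with flanking markers.

F2 plants are genotyped at a marker grid on the causal chromosome; a
recombinant is a plant whose marker genotype contradicts the causal genotype
its phenotype implies (dominant model: a normal plant must be aa, a speltoid
plant must carry A). The interval is bounded by the nearest markers with
strictly more recombinants than the minimum.
"""

import numpy as np

from bsakit import linkage, simdata

cfg = simdata.SimConfig(chromosomes=(("5A", 50_000_000),),
                        causal_locus=("5A", 40_000_000), n_f2=642, seed=1)
population = simdata.simulate_f2_population(cfg)

markers = [linkage.Marker(f"M{i + 1:02d}", "5A", int(p))
           for i, p in enumerate(np.arange(2_500_000, 50_000_000, 5_000_000))]
table = linkage.genotype_markers(population, markers)

for m in markers:
    recs = linkage.count_recombinants(table, m.id)
    print(f"{m.id}  {m.pos / 1e6:5.1f} Mb  {recs:3d} recombinants")

left, right, (lo, hi) = linkage.delimit_interval(table, markers,
                                                 chrom_length=50_000_000)
print(f"interval: 5A:{lo / 1e6:.1f}-{hi / 1e6:.1f} Mb "
      f"(flanked by {left.id if left else 'chrom start'} and "
      f"{right.id if right else 'chrom end'}; causal locus at 40.0 Mb)")

n_dom = (table.phenotype == simdata.SPELTOID).sum()
seg = linkage.chi_square_segregation(n_dom, len(table) - n_dom)
print(f"segregation {n_dom}:{len(table) - n_dom}, chi2={seg.chi2:.2f}, "
      f"p={seg.p_value:.2f} -> consistent with a single dominant gene (3:1)")
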