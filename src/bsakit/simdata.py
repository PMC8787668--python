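"""Synthetic data generation for the whole mapping pipeline.

Emulates the inputs of a bulked-segregant mapping experiment on an F2 cross
segregating one dominant causal allele: F2 genotypes built from recombinant
gametes (Haldane model, Poisson crossover counts), phenotype-contrasted bulks,
pooled allele depths over the SNP set (Poisson total depth, binomial allele
sampling), negative-binomial expression counts with implanted fold changes, and
TSS-proximal binding peaks with an implanted core motif.

All randomness flows from a single integer seed through per-operation child
streams (see :mod:`bsakit._rng`); identical (config, seed) pairs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .errors import ConfigurationError, SamplingError

logger = logging.getLogger("bsakit")

SPELTOID = "speltoid"
NORMAL = "normal"


@dataclass(frozen=True)
class SimConfig:
    """Study-design constants of the simulated cross.

    Defaults describe a desk-scale version of a hexaploid wheat F2 mapping
    population: the 21 wheat chromosomes (1A-7D) shrunk to 50 Mb each at
    1 cM/Mb, 10 SNPs/Mb, 642 F2 plants, two 50-plant phenotype-pure bulks
    sequenced to ~50x pooled depth, and one dominant causal allele near the
    end of chromosome 5A. The full karyotype matters: the candidate-region
    threshold is a genome-wide quantile, so the fraction of the genome the
    causal chromosome occupies sets how far regions extend down the dome of
    elevated dSNP-index around the causal locus.
    """

    chromosomes: tuple[tuple[str, int], ...] = tuple(
        (f"{n}{g}", 50_000_000) for n in range(1, 8) for g in "ABD"
    )
    snp_density: float = 10.0  # SNPs per Mb
    causal_locus: tuple[str, int] = ("5A", 40_000_000)
    dominant: bool = True
    n_f2: int = 642
    bulk_size: int = 50
    depth_lambda: float = 50.0
    parent_depth_lambda: float = 30.0
    map_function: float = 1.0  # cM per Mb
    misclassification_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("at least one chromosome required")
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name} has non-positive length")
        chrom, pos = self.causal_locus
        if chrom not in lengths or not (1 <= pos <= lengths[chrom]):
            raise ConfigurationError("causal locus must lie on a declared chromosome")
        if self.n_f2 <= 0:
            raise ConfigurationError("n_f2 must be positive")
        if self.bulk_size > self.n_f2 / 2:
            raise ConfigurationError("bulk_size must be <= n_f2/2")
        if self.depth_lambda <= 0 or self.parent_depth_lambda <= 0:
            raise ConfigurationError("depth parameters must be positive")
        if self.snp_density <= 0:
            raise ConfigurationError("snp_density must be positive")
        if not (0.0 <= self.misclassification_rate < 1.0):
            raise ConfigurationError("misclassification_rate must be in [0, 1)")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class F2Individual:
    """One F2 plant: two recombinant gametes per chromosome plus a phenotype.

    Each gamete is a mosaic of the two parental haplotypes, stored as sorted
    crossover breakpoints and the haplotype carried at the chromosome start
    (1 = mutant parent, 0 = wild-type parent). Genotype blocks therefore change
    only at crossover points.
    """

    id: int
    # chrom -> (breakpoints_g1, start_hap_g1, breakpoints_g2, start_hap_g2)
    gametes: dict[str, tuple[np.ndarray, int, np.ndarray, int]]
    phenotype: str = field(default=NORMAL)

    def dosage_at(self, chrom: str, positions) -> np.ndarray:
        """Count of mutant-parent alleles (0, 1 or 2) at each position."""
        bp1, s1, bp2, s2 = self.gametes[chrom]
        pos = np.atleast_1d(np.asarray(positions))
        h1 = (s1 + np.searchsorted(bp1, pos)) % 2
        h2 = (s2 + np.searchsorted(bp2, pos)) % 2
        return h1 + h2

    def genotype_at(self, chrom: str, pos: int) -> str:
        return {0: "aa", 1: "Aa", 2: "AA"}[int(self.dosage_at(chrom, pos)[0])]

    def genotype_track(self, positions_by_chrom: dict[str, np.ndarray]) -> dict[str, list[tuple[int, str]]]:
        code = {0: "aa", 1: "Aa", 2: "AA"}
        track: dict[str, list[tuple[int, str]]] = {}
        for chrom, pos in positions_by_chrom.items():
            dos = self.dosage_at(chrom, pos)
            track[chrom] = [(int(p), code[int(d)]) for p, d in zip(pos, dos)]
        return track


@dataclass(frozen=True)
class BulkPair:
    """Disjoint, phenotype-pure bulks of F2 plant ids."""

    mutant_bulk: tuple[int, ...]
    wt_bulk: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.mutant_bulk)

    def __post_init__(self) -> None:
        if set(self.mutant_bulk) & set(self.wt_bulk):
            raise ConfigurationError("bulks must be disjoint")


def _simulate_gametes(rng: np.random.Generator, n_gametes: int, length_bp: int,
                      cm_per_mb: float) -> list[tuple[np.ndarray, int]]:
    """Draw gametes under the Haldane model: Poisson crossover count, uniform placement."""
    lam = (length_bp / 1e6) * cm_per_mb / 100.0
    counts = rng.poisson(lam, size=n_gametes) if lam > 0 else np.zeros(n_gametes, dtype=int)
    starts = rng.integers(0, 2, size=n_gametes)
    total = int(counts.sum())
    flat = rng.uniform(0.0, float(length_bp), size=total)
    pieces = np.split(flat, np.cumsum(counts)[:-1]) if n_gametes else []
    return [(np.sort(p), int(s)) for p, s in zip(pieces, starts)]


def simulate_f2_population(config: SimConfig) -> list[F2Individual]:
    """Simulate an F2 population from a cross of two inbred parents.

    Both parents are fully homozygous and opposite at every marker, so the F1
    is heterozygous genome-wide and each F2 gamete is an independent
    recombinant of the two parental haplotypes. The phenotype follows the
    dominance model: a plant carrying at least one mutant allele at the causal
    locus is speltoid (dominant trait), otherwise normal.
    """
    rng = derive_rng(config.seed, "f2_population")
    n = config.n_f2
    per_chrom: dict[str, list[tuple[np.ndarray, int]]] = {}
    for chrom, length in config.chromosomes:
        per_chrom[chrom] = _simulate_gametes(rng, 2 * n, length, config.map_function)

    individuals: list[F2Individual] = []
    for i in range(n):
        gametes = {}
        for chrom, _ in config.chromosomes:
            g = per_chrom[chrom]
            bp1, s1 = g[2 * i]
            bp2, s2 = g[2 * i + 1]
            gametes[chrom] = (bp1, s1, bp2, s2)
        individuals.append(F2Individual(id=i, gametes=gametes))

    cchrom, cpos = config.causal_locus
    dosages = np.array([ind.dosage_at(cchrom, cpos)[0] for ind in individuals])
    carrier = dosages >= 1 if config.dominant else dosages == 2
    if config.misclassification_rate > 0:
        flips = rng.uniform(size=n) < config.misclassification_rate
        carrier = carrier ^ flips
    for ind, c in zip(individuals, carrier):
        ind.phenotype = SPELTOID if c else NORMAL
    return individuals


def build_bulks(population: list[F2Individual], bulk_size: int,
                seed: int = 0) -> BulkPair:
    """Sample two disjoint phenotype-pure bulks without replacement."""
    rng = derive_rng(seed, "build_bulks")
    spelt = [ind.id for ind in population if ind.phenotype == SPELTOID]
    normal = [ind.id for ind in population if ind.phenotype == NORMAL]
    for name, ids in ((SPELTOID, spelt), (NORMAL, normal)):
        if len(ids) < bulk_size:
            raise SamplingError(
                f"need {bulk_size} {name} plants but only {len(ids)} available "
                f"(deficit {bulk_size - len(ids)})"
            )
    mut = tuple(int(x) for x in rng.choice(spelt, size=bulk_size, replace=False))
    wt = tuple(int(x) for x in rng.choice(normal, size=bulk_size, replace=False))
    return BulkPair(mutant_bulk=mut, wt_bulk=wt)


def draw_snp_positions(config: SimConfig, seed: int | None = None) -> dict[str, np.ndarray]:
    """Draw SNP positions at the configured density; the causal locus is always a SNP."""
    rng = derive_rng(config.seed if seed is None else seed, "snp_positions")
    cchrom, cpos = config.causal_locus
    positions: dict[str, np.ndarray] = {}
    for chrom, length in config.chromosomes:
        n = max(1, int(round(config.snp_density * length / 1e6)))
        pos = np.unique(rng.integers(1, length + 1, size=n))
        if chrom == cchrom:
            pos = np.unique(np.concatenate([pos, [cpos]]))
        positions[chrom] = pos.astype(np.int64)
    return positions


_EMS_ALT = {"G": "A", "C": "T"}


def simulate_bulk_readcounts(bulks: BulkPair, population: list[F2Individual],
                             snp_positions: dict[str, np.ndarray],
                             depth_lambda: float, seed: int = 0,
                             parent_depth_lambda: float = 30.0) -> pd.DataFrame:
    """Emulate pooled whole-exome allele depths for the two bulks and the parents.

    Per locus and bulk, total depth ~ Poisson(depth_lambda) and mutant-allele
    reads ~ Binomial(depth, f) where f is the mutant-allele frequency among the
    bulk's members at that locus. The mutant parent is homozygous for the ALT
    (EMS-derived) allele at every SNP, the wild-type parent for REF, each with
    Poisson parental depth.
    """
    rng = derive_rng(seed, "bulk_readcounts")
    by_id = {ind.id: ind for ind in population}
    frames = []
    for chrom in snp_positions:
        pos = np.asarray(snp_positions[chrom])
        m = len(pos)
        freqs = {}
        for label, ids in (("mut", bulks.mutant_bulk), ("wt", bulks.wt_bulk)):
            dosage = np.zeros(m, dtype=np.int64)
            for i in ids:
                dosage += by_id[i].dosage_at(chrom, pos)
            freqs[label] = dosage / (2.0 * len(ids))
        ref = rng.choice(np.array(["G", "C"]), size=m)
        alt = np.array([_EMS_ALT[b] for b in ref])
        dp_mut = rng.poisson(depth_lambda, size=m)
        dp_wt = rng.poisson(depth_lambda, size=m)
        pa_dp = rng.poisson(parent_depth_lambda, size=m)
        pb_dp = rng.poisson(parent_depth_lambda, size=m)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "pA_ref": 0,
            "pA_alt": pa_dp,
            "pB_ref": pb_dp,
            "pB_alt": 0,
            "bulk_mut_alt": rng.binomial(dp_mut, freqs["mut"]),
            "bulk_mut_dp": dp_mut,
            "bulk_wt_alt": rng.binomial(dp_wt, freqs["wt"]),
            "bulk_wt_dp": dp_wt,
        }))
    out = pd.concat(frames, ignore_index=True)
    logger.info("simulated read counts at %d loci over %d chromosomes", len(out), len(snp_positions))
    return out


def table_from_category_counts(n_low_depth: int, n_monomorphic: int, n_retained: int,
                               seed: int = 0) -> pd.DataFrame:
    """Build a SNP table with exact per-filter-category totals.

    Used to validate filter accounting at realistic scale: ``n_low_depth`` loci
    have a parent sequenced below any usual depth cutoff, ``n_monomorphic``
    pass depth but share the parental genotype, ``n_retained`` are clean
    opposite-homozygote loci.
    """
    rng = derive_rng(seed, "category_table")
    n = n_low_depth + n_monomorphic + n_retained
    pa_ref = np.zeros(n, dtype=np.int64)
    pa_alt = np.zeros(n, dtype=np.int64)
    pb_ref = np.zeros(n, dtype=np.int64)
    pb_alt = np.zeros(n, dtype=np.int64)

    lo = slice(0, n_low_depth)
    pa_ref[lo] = rng.integers(0, 4, size=n_low_depth)  # parent A depth < 4
    pb_ref[lo] = rng.integers(0, 60, size=n_low_depth)

    mono = slice(n_low_depth, n_low_depth + n_monomorphic)
    d = rng.integers(4, 60, size=n_monomorphic)
    pa_ref[mono] = d  # both parents homozygous REF
    pb_ref[mono] = rng.integers(4, 60, size=n_monomorphic)

    keep = slice(n_low_depth + n_monomorphic, n)
    pa_alt[keep] = rng.integers(4, 60, size=n_retained)  # opposite homozygotes
    pb_ref[keep] = rng.integers(4, 60, size=n_retained)

    dp = rng.poisson(40, size=n)
    table = pd.DataFrame({
        "chrom": np.char.add("chr", ((np.arange(n) % 21) + 1).astype(str)),
        "pos": np.arange(1, n + 1, dtype=np.int64),
        "ref": "G",
        "alt": "A",
        "pA_ref": pa_ref,
        "pA_alt": pa_alt,
        "pB_ref": pb_ref,
        "pB_alt": pb_alt,
        "bulk_mut_alt": rng.binomial(dp, 0.5),
        "bulk_mut_dp": dp,
        "bulk_wt_alt": 0,
        "bulk_wt_dp": rng.poisson(40, size=n),
    })
    return table.sample(frac=1.0, random_state=int(derive_rng(seed, "shuffle").integers(2**31))).reset_index(drop=True)


def simulate_gene_models(chromosomes: tuple[tuple[str, int], ...], n_genes: int,
                         seed: int = 0, min_len: int = 2_000, max_len: int = 6_000,
                         margin: int = 20_000) -> pd.DataFrame:
    """Place stranded single-transcript gene models uniformly along the chromosomes."""
    rng = derive_rng(seed, "gene_models")
    rows = []
    chrom_names = [c for c, _ in chromosomes]
    lengths = dict(chromosomes)
    which = rng.integers(0, len(chrom_names), size=n_genes)
    for g in range(n_genes):
        chrom = chrom_names[which[g]]
        glen = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(margin, lengths[chrom] - margin - glen))
        strand = "+" if rng.uniform() < 0.5 else "-"
        end = start + glen - 1
        rows.append({
            "gene_id": f"gene{g:05d}",
            "chrom": chrom,
            "start": start,  # 1-based inclusive
            "end": end,
            "strand": strand,
            "tss": start if strand == "+" else end,
        })
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_expression_counts(n_genes: int, n_reps: int, de_fraction: float,
                               fold: float, dispersion: float, seed: int = 0,
                               mean_log: float = 5.3, mean_sigma: float = 1.0
                               ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial count matrix for two groups with implanted fold changes.

    Returns (counts, gene lengths in bp, truth table). ``de_fraction`` of genes
    have their group-B mean multiplied (up) or divided (down) by ``fold``;
    variance follows mean + dispersion * mean^2 (dispersion 0 gives Poisson).
    """
    if fold <= 0:
        raise ConfigurationError("fold must be positive")
    if n_reps < 2:
        raise ConfigurationError("need at least 2 replicates per group")
    if not (0.0 <= de_fraction <= 1.0):
        raise ConfigurationError("de_fraction must be in [0, 1]")
    rng = derive_rng(seed, "expression_counts")
    base = rng.lognormal(mean=mean_log, sigma=mean_sigma, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    direction = np.array([""] * n_genes, dtype=object)
    direction[de_idx[: n_de // 2]] = "up"
    direction[de_idx[n_de // 2:]] = "down"
    mult = np.ones(n_genes)
    mult[direction == "up"] = fold
    mult[direction == "down"] = 1.0 / fold

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion <= 0:
            return rng.poisson(mu)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu))

    samples = {}
    for j in range(n_reps):
        samples[f"A{j + 1}"] = draw(base)
    for j in range(n_reps):
        samples[f"B{j + 1}"] = draw(base * mult)
    genes = [f"gene{g:05d}" for g in range(n_genes)]
    counts = pd.DataFrame(samples, index=pd.Index(genes, name="gene_id"))
    lengths = pd.Series(rng.integers(500, 5001, size=n_genes), index=counts.index, name="length")
    truth = pd.DataFrame({
        "is_de": direction != "",
        "direction": direction,
        "true_fold": mult,
    }, index=counts.index)
    return counts, lengths, truth


_SAFE_CODONS = ["GCA", "GCC", "GCG", "GCT", "TTC", "AAG", "GAC", "CTG",
                "ATC", "GGA", "CCT", "GTG"]


def synthetic_causal_gene(seed: int = 7):
    """A synthetic 10-exon gene mirroring the mapped locus's printed architecture.

    Returns ``(gene, snv_pos, ref, alt)``: a plus-strand gene with a 1,344-nt
    CDS (447-aa product), an in-frame 117-nt exon 9 (codons 351-389, so the
    exon-9-skip isoform encodes 408 aa), an intron 8 that opens with an
    in-frame stop, two protein domains, and a G-to-A SNV in exon 5 that turns
    codon 224 (TGG) into a stop — truncating the product to 223 aa and
    creating a DdeI site (CTGGG -> CTGAG). Synthetic stand-in for the real
    locus; the architecture, not the base sequence, is what it reproduces.
    """
    from .mutfx import GeneModelCds  # local import avoids a cycle at module load

    rng = derive_rng(seed, "causal_gene")
    exon_lens = [150, 120, 150, 120, 150, 120, 120, 120, 117, 177]
    n_codons = sum(exon_lens) // 3  # 448 incl. stop
    codons = [str(c) for c in rng.choice(_SAFE_CODONS, size=n_codons)]
    codons[0] = "ATG"
    codons[222] = "GCC"  # ends with C: 5' half of the DdeI window
    codons[223] = "TGG"  # G-to-A at its third base gives TGA (stop)
    codons[224] = "GGA"  # starts with G: completes CTGGG on the WT allele
    codons[-1] = "TAA"
    cds = "".join(codons)

    bases = np.array(list("ACGT"))
    intron_len = 80
    introns = ["".join(rng.choice(bases, size=intron_len)) for _ in range(9)]
    introns[7] = "TAA" + introns[7][3:]  # in-frame stop when intron 8 is retained

    flank = "".join(rng.choice(bases, size=100))
    flank2 = "".join(rng.choice(bases, size=100))
    parts, exons, cursor = [flank], [], len(flank)
    off = 0
    for i, L in enumerate(exon_lens):
        parts.append(cds[off:off + L])
        exons.append((cursor + 1, cursor + L))
        cursor += L
        off += L
        if i < 9:
            parts.append(introns[i])
            cursor += intron_len
    parts.append(flank2)
    genomic = "".join(parts)

    gene = GeneModelCds(
        gene_id="synthQ", genomic_seq=genomic, exons=tuple(exons), strand="+",
        domains=(("AP2-1", 120, 180), ("AP2-2", 270, 330)),
    )
    cds_idx = 223 * 3 + 2  # third base of codon 224, 0-based
    within_e5 = cds_idx - sum(exon_lens[:4])
    snv_pos = exons[4][0] + within_e5
    assert genomic[snv_pos - 1] == "G"
    return gene, snv_pos, "G", "A"


def make_amplicon_pair(seed: int = 0, length: int = 395,
                       site_wt: str = "CTGGG", site_mut: str = "CTGAG"):
    """A synthetic CAPS amplicon pair: one DdeI site gained by the mutant allele.

    The WT amplicon carries no DdeI (CTNAG) site anywhere; the mutant differs
    at a single base in the centre, where CTGGG becomes CTGAG. Returns
    ``(amplicon_wt, amplicon_mut)``.
    """
    import re

    rng = derive_rng(seed, "amplicon")
    bases = np.array(list("ACGT"))
    pat = re.compile("(?=CT[ACGT]AG)")
    for _ in range(1000):
        seq = "".join(rng.choice(bases, size=length))
        c = length // 2
        wt = seq[:c - 2] + site_wt + seq[c + 3:]
        mut = seq[:c - 2] + site_mut + seq[c + 3:]
        if not pat.search(wt) and len(pat.findall(mut)) == 1:
            return wt, mut
    raise RuntimeError("could not construct a clean amplicon pair")  # pragma: no cover


def simulate_peaks_and_sequences(genes: pd.DataFrame, n_target: int,
                                 motif: str = "CTTGC",
                                 window: tuple[int, int] = (-2_000, 500),
                                 n_peaks: int = 200, peak_width: int = 100,
                                 chrom_lengths: dict[str, int] | None = None,
                                 implant_fraction: float | None = None,
                                 seed: int = 0) -> tuple[pd.DataFrame, dict[str, str]]:
    """Place binding peaks, ``n_target`` of them inside the TSS window of chosen genes.

    Target peaks get the motif implanted at a random offset in their sequence;
    the rest are placed uniformly. ``implant_fraction`` overrides the default
    targets-only implanting (e.g. 1.0 implants the motif in every peak, the
    setup for motif-recovery checks). Peaks are returned in BED convention
    (0-based half-open).
    """
    if len(motif) < 3:
        raise ConfigurationError("motif length must be >= 3")
    if n_target > len(genes):
        raise ConfigurationError("n_target exceeds number of genes")
    if n_target > n_peaks:
        raise ConfigurationError("n_target exceeds n_peaks")
    rng = derive_rng(seed, "peaks")
    if chrom_lengths is None:
        chrom_lengths = {c: int(g["end"].max()) + 50_000 for c, g in genes.groupby("chrom")}
    lo, hi = window
    for c in genes["chrom"].unique():
        if hi - lo + peak_width >= chrom_lengths[c]:
            raise ConfigurationError("window inconsistent with chromosome bounds")
    target_rows = genes.iloc[rng.choice(len(genes), size=n_target, replace=False)]
    rows = []
    for i, (_, g) in enumerate(target_rows.iterrows()):
        d = int(rng.integers(lo, hi + 1))
        anchor = g["tss"] + d if g["strand"] == "+" else g["tss"] - d  # 1-based
        start = max(0, int(anchor) - 1 - peak_width // 2)
        start = min(start, chrom_lengths[g["chrom"]] - peak_width)
        rows.append({"chrom": g["chrom"], "start": start, "end": start + peak_width,
                     "name": f"peak{i:05d}", "score": float(rng.uniform(5, 50)),
                     "is_target_truth": True, "target_gene_truth": g["gene_id"]})
    chrom_names = sorted(chrom_lengths)
    for i in range(n_target, n_peaks):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        start = int(rng.integers(0, chrom_lengths[chrom] - peak_width))
        rows.append({"chrom": chrom, "start": start, "end": start + peak_width,
                     "name": f"peak{i:05d}", "score": float(rng.uniform(5, 50)),
                     "is_target_truth": False, "target_gene_truth": ""})
    peaks = pd.DataFrame(rows)

    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    for _, p in peaks.iterrows():
        seq = "".join(rng.choice(bases, size=peak_width))
        implant = p["is_target_truth"] if implant_fraction is None else bool(rng.uniform() < implant_fraction)
        if implant:
            off = int(rng.integers(0, peak_width - len(motif) + 1))
            seq = seq[:off] + motif + seq[off + len(motif):]
        seqs[p["name"]] = seq
    return peaks, seqs
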