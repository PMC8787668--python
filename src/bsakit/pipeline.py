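"""End-to-end orchestration: simulate -> filter -> scan -> map -> markers -> effects -> express -> targets.

Each stage reads only files earlier stages wrote, records its outputs with
checksums in a run manifest, and is skipped on re-run when its outputs are
intact. Identical (config, seed) pairs produce bit-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsascan, daptargets, expression, io, linkage, markerdesign, mutfx, simdata, snpfilter

logger = logging.getLogger("bsakit")

DEFAULT_CONFIG: dict = {
    "simdata": {
        "chromosomes": [[f"{n}{g}", 50_000_000] for n in range(1, 8) for g in "ABD"],
        "snp_density": 10.0,
        "causal_locus": ["5A", 40_000_000],
        "dominant": True,
        "n_f2": 642,
        "bulk_size": 50,
        "depth_lambda": 50.0,
        "parent_depth_lambda": 30.0,
        "map_function": 1.0,
        "misclassification_rate": 0.0,
        "n_genes": 500,
        "marker_spacing_bp": 5_000_000,
        "expression": {"n_reps": 3, "de_fraction": 0.1, "fold": 4.0, "dispersion": 0.01},
        "peaks": {"n_peaks": 200, "n_target": 20, "motif": "CTTGC", "peak_width": 100},
    },
    "snpfilter": {"min_depth": 4, "purity": 0.9, "depth_mode": "either"},
    "bsascan": {"span": 0.1, "degree": 1, "iterations": 2, "quantile": 0.99},
    "markerdesign": {"primer_len": 21},
    "expression": {"fc_threshold": 2.0, "q_threshold": 0.05, "min_mean_fpkm": 1.0},
    "daptargets": {"k": 5, "n_shuffles": 10},
}

STAGES = ("simulate", "filter", "scan", "map", "markers", "effects", "express", "targets")


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config(cfg: dict, seed: int) -> simdata.SimConfig:
    s = cfg["simdata"]
    return simdata.SimConfig(
        chromosomes=tuple((c, int(L)) for c, L in s["chromosomes"]),
        snp_density=s["snp_density"],
        causal_locus=(s["causal_locus"][0], int(s["causal_locus"][1])),
        dominant=s["dominant"], n_f2=s["n_f2"], bulk_size=s["bulk_size"],
        depth_lambda=s["depth_lambda"], parent_depth_lambda=s["parent_depth_lambda"],
        map_function=s["map_function"],
        misclassification_rate=s["misclassification_rate"], seed=seed,
    )


def _marker_grid(sim: simdata.SimConfig, spacing: int) -> list[linkage.Marker]:
    chrom = sim.causal_locus[0]
    length = sim.chrom_lengths[chrom]
    positions = np.arange(spacing // 2, length, spacing)
    return [linkage.Marker(id=f"M{i + 1:02d}", chrom=chrom, pos=int(p))
            for i, p in enumerate(positions)]


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    sim = _sim_config(cfg, seed)
    s = cfg["simdata"]
    population = simdata.simulate_f2_population(sim)
    bulks = simdata.build_bulks(population, sim.bulk_size, seed=seed)
    positions = simdata.draw_snp_positions(sim)
    table = simdata.simulate_bulk_readcounts(
        bulks, population, positions, sim.depth_lambda, seed=seed,
        parent_depth_lambda=sim.parent_depth_lambda)
    io.write_vcf(table, outdir / "snps.vcf", contig_lengths=sim.chrom_lengths)

    markers = _marker_grid(sim, int(s["marker_spacing_bp"]))
    geno = linkage.genotype_markers(population, markers)
    marker_meta = pd.DataFrame([{"id": m.id, "chrom": m.chrom, "pos": m.pos} for m in markers])
    io.write_tsv(marker_meta, outdir / "marker_positions.tsv")
    io.write_tsv(geno.reset_index(), outdir / "marker_genotypes.tsv")

    genes = simdata.simulate_gene_models(sim.chromosomes, int(s["n_genes"]), seed=seed)
    io.write_gff3(genes, outdir / "genes.gff3")

    e = s["expression"]
    counts, lengths, truth = simdata.simulate_expression_counts(
        n_genes=int(s["n_genes"]), n_reps=int(e["n_reps"]), de_fraction=e["de_fraction"],
        fold=e["fold"], dispersion=e["dispersion"], seed=seed)
    io.write_tsv(counts.reset_index(), outdir / "expr_counts.tsv")
    io.write_tsv(lengths.reset_index(), outdir / "expr_lengths.tsv")
    io.write_tsv(truth.reset_index(), outdir / "expr_truth.tsv")

    p = s["peaks"]
    peaks, seqs = simdata.simulate_peaks_and_sequences(
        genes, n_target=int(p["n_target"]), motif=p["motif"], n_peaks=int(p["n_peaks"]),
        peak_width=int(p["peak_width"]), chrom_lengths=sim.chrom_lengths, seed=seed)
    io.write_bed(peaks.assign(strand="."), outdir / "peaks.bed")
    io.write_tsv(peaks, outdir / "peaks_truth.tsv")
    io.write_fasta(seqs, outdir / "peak_seqs.fasta")
    return [outdir / f for f in ("snps.vcf", "marker_positions.tsv", "marker_genotypes.tsv",
                                 "genes.gff3", "expr_counts.tsv", "expr_lengths.tsv",
                                 "expr_truth.tsv", "peaks.bed", "peaks_truth.tsv",
                                 "peak_seqs.fasta")]


def stage_filter(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    f = cfg["snpfilter"]
    table = io.read_vcf(outdir / "snps.vcf")
    kept, acc = snpfilter.run_filters(table, min_depth=int(f["min_depth"]),
                                      purity=f["purity"], depth_mode=f["depth_mode"])
    io.write_vcf(kept, outdir / "snps.filtered.vcf")
    io.write_tsv(acc.to_frame(), outdir / "filter_accounting.tsv")
    return [outdir / "snps.filtered.vcf", outdir / "filter_accounting.tsv"]


def stage_scan(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    b = cfg["bsascan"]
    table = io.read_vcf(outdir / "snps.filtered.vcf")
    track, regions = bsascan.scan(table, span=b["span"], degree=int(b["degree"]),
                                  iterations=int(b["iterations"]), quantile=b["quantile"])
    io.write_tsv(track, outdir / "delta_index_track.tsv")
    io.regions_to_bed(regions, outdir / "candidate_regions.bed")
    return [outdir / "delta_index_track.tsv", outdir / "candidate_regions.bed"]


def stage_map(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    meta = io.read_tsv(outdir / "marker_positions.tsv")
    geno = io.read_tsv(outdir / "marker_genotypes.tsv", index_col="individual")
    markers = [linkage.Marker(r["id"], r["chrom"], int(r["pos"])) for _, r in meta.iterrows()]
    chrom_len = dict((c, int(L)) for c, L in cfg["simdata"]["chromosomes"])[markers[0].chrom]
    counts = pd.DataFrame({
        "marker": [m.id for m in markers],
        "pos": [m.pos for m in markers],
        "recombinants": [linkage.count_recombinants(geno, m.id) for m in markers],
    })
    left, right, (lo, hi) = linkage.delimit_interval(geno, markers, chrom_length=chrom_len)
    io.write_tsv(counts, outdir / "recombinant_counts.tsv")
    interval = pd.DataFrame([{"chrom": markers[0].chrom, "start": lo - 1, "end": hi,
                              "name": "candidate_interval", "score": 0, "strand": "."}])
    io.write_bed(interval, outdir / "interval.bed")
    n_dom = int((geno["phenotype"] == simdata.SPELTOID).sum())
    n_rec = int((geno["phenotype"] == simdata.NORMAL).sum())
    seg = linkage.chi_square_segregation(n_dom, n_rec)
    report = (
        f"candidate interval: {markers[0].chrom}:{lo}-{hi}\n"
        f"flanking markers: {left.id if left else 'chrom start'} / "
        f"{right.id if right else 'chrom end'}\n"
        f"segregation: {n_dom} dominant : {n_rec} recessive, "
        f"chi2={seg.chi2:.3f}, p={seg.p_value:.3f} (3:1 expectation)\n"
    )
    (outdir / "mapping_report.txt").write_text(report)
    return [outdir / "recombinant_counts.tsv", outdir / "interval.bed",
            outdir / "mapping_report.txt"]


def stage_markers(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    amp_wt, amp_mut = simdata.make_amplicon_pair(seed=seed)
    io.write_fasta({"amplicon_wt": amp_wt, "amplicon_mut": amp_mut}, outdir / "amplicons.fasta")
    assays = markerdesign.design_caps(amp_wt, amp_mut)
    rows = [{"enzyme": a.enzyme.name,
             "bands_wt": ",".join(map(str, a.bands_wt)),
             "bands_mut": ",".join(map(str, a.bands_mut)),
             "bands_het": ",".join(map(str, a.bands_het)),
             "separability": a.separability} for a in assays]
    io.write_tsv(pd.DataFrame(rows), outdir / "caps_assays.tsv")

    c = len(amp_wt) // 2
    kasp = markerdesign.design_kasp(amp_wt[:c + 1], amp_wt[c + 1], amp_mut[c + 1],
                                    amp_wt[c + 2:], primer_len=int(cfg["markerdesign"]["primer_len"]))
    io.write_tsv(pd.DataFrame([{
        "allele1_forward": kasp.allele1_forward,
        "allele2_forward": kasp.allele2_forward,
        "common_reverse": kasp.common_reverse,
    }]), outdir / "kasp_assay.tsv")
    return [outdir / "amplicons.fasta", outdir / "caps_assays.tsv", outdir / "kasp_assay.tsv"]


def stage_effects(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    gene, pos, ref, alt = simdata.synthetic_causal_gene()
    eff = mutfx.apply_snv_and_classify(gene, pos, ref, alt)
    io.write_tsv(pd.DataFrame([{
        "gene": gene.gene_id, "pos": pos, "ref": ref, "alt": alt,
        "class": eff.effect_class, "codon": eff.codon_index,
        "ref_aa": eff.ref_aa, "alt_aa": eff.alt_aa,
        "wt_len": eff.wt_protein_length, "mut_len": eff.mut_protein_length,
        "lost_domains": ",".join(eff.lost_domains),
    }]), outdir / "variant_effects.tsv")

    isoforms = [mutfx.splice_isoform(gene, ev, iso_id) for ev, iso_id in
                ((("full",), "T1"), (("exon_skip", 9), "T2"), (("intron_retention", 8), "T3"))]
    io.write_tsv(pd.DataFrame([{
        "isoform": p.isoform_id, "event": "_".join(map(str, p.event)),
        "transcript_nt": len(p.transcript), "protein_aa": len(p.protein),
        "termination_aa": p.termination_aa, "no_product": p.no_product,
    } for p in isoforms]), outdir / "isoforms.tsv")
    io.write_fasta({p.isoform_id: p.protein for p in isoforms if p.protein},
                   outdir / "isoform_proteins.fasta")
    return [outdir / "variant_effects.tsv", outdir / "isoforms.tsv",
            outdir / "isoform_proteins.fasta"]


def stage_express(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    e = cfg["expression"]
    counts = io.read_tsv(outdir / "expr_counts.tsv", index_col="gene_id")
    lengths = io.read_tsv(outdir / "expr_lengths.tsv", index_col="gene_id")["length"]
    n_reps = int(cfg["simdata"]["expression"]["n_reps"])
    groups = {"A": [f"A{i + 1}" for i in range(n_reps)],
              "B": [f"B{i + 1}" for i in range(n_reps)]}
    degs = expression.call_degs(counts, lengths, groups, fc_threshold=e["fc_threshold"],
                                q_threshold=e["q_threshold"], min_mean_fpkm=e["min_mean_fpkm"])
    io.write_tsv(degs.reset_index(), outdir / "degs.tsv")
    return [outdir / "degs.tsv"]


def stage_targets(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    d = cfg["daptargets"]
    genes = io.read_gff3(outdir / "genes.gff3")
    peaks = io.read_bed(outdir / "peaks.bed")
    seqs = io.read_fasta(outdir / "peak_seqs.fasta")
    degs = io.read_tsv(outdir / "degs.tsv", index_col="gene_id")
    assignments = daptargets.assign_peaks(peaks, genes)
    targets = daptargets.putative_targets(assignments)
    down, up = daptargets.intersect_degs(targets, degs)
    io.write_tsv(assignments, outdir / "peak_assignments.tsv")
    io.write_tsv(pd.DataFrame({"gene_id": sorted(targets)}), outdir / "putative_targets.tsv")
    io.write_tsv(pd.DataFrame(
        [{"gene_id": g, "direction": "down"} for g in sorted(down)]
        + [{"gene_id": g, "direction": "up"} for g in sorted(up)]),
        outdir / "target_degs.tsv")
    motifs = daptargets.kmer_enrichment([seqs[n] for n in sorted(seqs)],
                                        k=int(d["k"]), n_shuffles=int(d["n_shuffles"]), seed=seed)
    io.write_tsv(motifs.head(100), outdir / "motif_enrichment.tsv")
    return [outdir / "peak_assignments.tsv", outdir / "putative_targets.tsv",
            outdir / "target_degs.tsv", outdir / "motif_enrichment.tsv"]


_STAGE_FUNCS = {
    "simulate": stage_simulate, "filter": stage_filter, "scan": stage_scan,
    "map": stage_map, "markers": stage_markers, "effects": stage_effects,
    "express": stage_express, "targets": stage_targets,
}


def run_all(config: dict | None = None, outdir: str | Path = "bsakit_run",
            seed: int = 0, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the pipeline end to end, resuming over intact stage outputs.

    Returns the run manifest (also written to ``manifest.json``): config
    snapshot, seed, per-stage outputs with SHA-256 checksums, timings and
    captured warnings.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = {"config": cfg, "seed": seed, "stages": {}}
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})

    io.write_config(cfg, outdir / "config.yaml")
    for name in stages:
        prev = previous.get(name)
        if prev and all(Path(p).exists() and _sha256(Path(p)) == h
                        for p, h in prev["outputs"].items()):
            logger.info("stage %s: outputs intact, skipped", name)
            manifest["stages"][name] = {**prev, "skipped": True}
            continue
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            outputs = _STAGE_FUNCS[name](cfg, outdir, seed)
        manifest["stages"][name] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "warnings": [str(w.message) for w in caught],
            "skipped": False,
        }
        logger.info("stage %s: %d outputs in %.2fs", name, len(outputs),
                    manifest["stages"][name]["elapsed_s"])
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
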