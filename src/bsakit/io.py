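"""Readers and writers for the pipeline's on-disk formats.

The SNP table travels as minimal VCF 4.2 (CHROM/POS/REF/ALT with per-sample
AD and DP over four samples: the two parents and the two bulks), gene models
as GFF3, peaks as BED 6, matrices and tracks as headered TSV, configuration
as YAML. Every writer has a matching reader and round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SAMPLES = ("PARENT_MUT", "PARENT_WT", "BULK_MUT", "BULK_WT")

_VCF_COLUMNS = {
    "PARENT_MUT": ("pA_ref", "pA_alt"),
    "PARENT_WT": ("pB_ref", "pB_alt"),
    "BULK_MUT": None,  # alt reads = bulk_mut_alt, dp = bulk_mut_dp
    "BULK_WT": None,
}


def write_vcf(table: pd.DataFrame, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write the SNP table as an uncompressed VCF 4.2 with AD/DP per sample."""
    path = Path(path)
    if contig_lengths is None:
        contig_lengths = {c: int(g["pos"].max()) + 1 for c, g in table.groupby("chrom", sort=False)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in sorted(contig_lengths):
            fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(SAMPLES) + "\n")
        cols = table[["chrom", "pos", "ref", "alt", "pA_ref", "pA_alt", "pB_ref", "pB_alt",
                      "bulk_mut_alt", "bulk_mut_dp", "bulk_wt_alt", "bulk_wt_dp"]].to_numpy()
        lines = []
        for (chrom, pos, ref, alt, pa_r, pa_a, pb_r, pb_a, bm_a, bm_dp, bw_a, bw_dp) in cols:
            samples = [
                f"{pa_r},{pa_a}:{pa_r + pa_a}",
                f"{pb_r},{pb_a}:{pb_r + pb_a}",
                f"{bm_dp - bm_a},{bm_a}:{bm_dp}",
                f"{bw_dp - bw_a},{bw_a}:{bw_dp}",
            ]
            lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tAD:DP\t" + "\t".join(samples))
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into the SNP-table schema."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            s = rec.samples
            pa = s["PARENT_MUT"]["AD"]
            pb = s["PARENT_WT"]["AD"]
            bm = s["BULK_MUT"]["AD"]
            bw = s["BULK_WT"]["AD"]
            rows.append({
                "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alts[0],
                "pA_ref": pa[0], "pA_alt": pa[1],
                "pB_ref": pb[0], "pB_alt": pb[1],
                "bulk_mut_alt": bm[1], "bulk_mut_dp": bm[0] + bm[1],
                "bulk_wt_alt": bw[1], "bulk_wt_dp": bw[0] + bw[1],
            })
    df = pd.DataFrame(rows)
    for c in df.columns:
        if c not in ("chrom", "ref", "alt"):
            df[c] = df[c].astype(np.int64)
    return df


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models (gene_id, chrom, start, end, strand) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(f'{g["chrom"]}\tbsakit\tgene\t{g["start"]}\t{g["end"]}\t.\t'
                     f'{g["strand"]}\t.\tID={g["gene_id"]}\n')


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene features from a GFF3 into the gene-model frame (with TSS)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"])
    df = df[df["type"] == "gene"].copy()
    df["gene_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    return df[["gene_id", "chrom", "start", "end", "strand", "tss"]].reset_index(drop=True)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write BED 6 (chrom, start, end, name, score, strand); missing columns filled."""
    df = intervals.copy()
    if "name" not in df:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def regions_to_bed(regions, path: str | Path) -> None:
    """Write candidate regions as BED (1-based inclusive -> 0-based half-open)."""
    rows = [{"chrom": r.chrom, "start": r.start - 1, "end": r.end,
             "name": f"region{i}", "score": round(r.peak_fitted, 4), "strand": "."}
            for i, r in enumerate(regions)]
    write_bed(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]), path)
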