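"""Coding-effect prediction: point mutations, truncations, splice isoforms, miRNA sites.

Works on a minimal gene model (genomic exon coordinates on a supplied genomic
sequence, plus protein-coordinate domain annotations) and answers the
questions asked of an EMS-induced candidate mutation: does the SNV silence,
substitute or truncate the protein, which domains fall beyond a premature
stop, what do declared alternative-splicing events (exon skips, intron
retentions) translate to, and how many mismatches does a miRNA target site
carry.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import DataError, SequenceError

_DNA = re.compile("[^ACGT]")


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    if _DNA.search(seq):
        raise SequenceError("sequence contains non-ACGT characters")
    return seq


def translate(cds: str) -> str:
    """Translate a CDS with the standard code, stopping at the first stop codon."""
    cds = _check_seq(cds)
    if len(cds) < 3:
        raise SequenceError("CDS shorter than one codon")
    if not cds.startswith("ATG"):
        warnings.warn("CDS does not start with ATG")
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


@dataclass(frozen=True)
class GeneModelCds:
    """A coding gene model: exons on a genomic sequence, strand, protein domains.

    ``exons`` are 1-based inclusive coordinates on ``genomic_seq`` (which may be
    a chromosome or just the locus), stored in genomic order; for minus-strand
    genes the transcript reads them 3'->5' and is reverse-complemented.
    ``domains`` are (name, aa_start, aa_end) in protein coordinates.
    """

    gene_id: str
    genomic_seq: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    domains: tuple[tuple[str, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "genomic_seq", _check_seq(self.genomic_seq))
        ex = sorted(self.exons)
        if any(s > e or s < 1 or e > len(self.genomic_seq) for s, e in ex):
            raise DataError("exon outside genomic sequence or inverted")
        if any(a[1] >= b[0] for a, b in zip(ex, ex[1:])):
            raise DataError("exons overlap")
        if self.strand not in "+-":
            raise DataError("strand must be + or -")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_seq(self, k: int) -> str:
        """Exon k (1-based, transcript order) on the coding strand."""
        s, e = self._exon_genomic(k)
        seq = self.genomic_seq[s - 1:e]
        return _rc(seq) if self.strand == "-" else seq

    def intron_seq(self, k: int) -> str:
        """Intron k (between transcript exons k and k+1) on the coding strand."""
        if not (1 <= k <= self.n_exons - 1):
            raise DataError(f"no intron {k}")
        if self.strand == "+":
            s = self.exons[k - 1][1] + 1
            e = self.exons[k][0] - 1
            return self.genomic_seq[s - 1:e]
        s = self.exons[-k - 1][1] + 1
        e = self.exons[-k][0] - 1
        return _rc(self.genomic_seq[s - 1:e])

    def _exon_genomic(self, k: int) -> tuple[int, int]:
        if not (1 <= k <= self.n_exons):
            raise DataError(f"no exon {k}")
        return self.exons[k - 1] if self.strand == "+" else self.exons[-k]

    def cds(self) -> str:
        return "".join(self.exon_seq(k) for k in range(1, self.n_exons + 1))

    def protein(self) -> str:
        return translate(self.cds())

    def genomic_to_cds(self, pos: int) -> int:
        """Map a genomic position inside an exon to a 0-based CDS index."""
        offset = 0
        for k in range(1, self.n_exons + 1):
            s, e = self._exon_genomic(k)
            if s <= pos <= e:
                within = (pos - s) if self.strand == "+" else (e - pos)
                return offset + within
            offset += e - s + 1
        raise DataError(f"position {pos} is not exonic (intronic variants unsupported)")


_RC = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class VariantEffect:
    """Predicted coding consequence of a single-nucleotide variant."""

    effect_class: str  # silent | missense | nonsense
    codon_index: int  # 1-based
    ref_aa: str
    alt_aa: str
    wt_protein_length: int
    mut_protein_length: int
    lost_domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.effect_class == "nonsense":
            assert self.mut_protein_length < self.wt_protein_length
        if self.effect_class == "silent":
            assert self.mut_protein_length == self.wt_protein_length
            assert self.ref_aa == self.alt_aa


def apply_snv_and_classify(gene: GeneModelCds, genomic_pos: int, ref: str, alt: str) -> VariantEffect:
    """Apply an exonic SNV, retranslate, and classify its coding effect.

    ``ref``/``alt`` are forward-strand genomic bases; a nonsense effect reports
    every domain whose protein interval extends beyond the truncated product.
    """
    ref, alt = ref.upper(), alt.upper()
    if gene.genomic_seq[genomic_pos - 1] != ref:
        raise DataError(f"reference mismatch at {genomic_pos}: model has "
                        f"{gene.genomic_seq[genomic_pos - 1]}, variant says {ref}")
    cds_idx = gene.genomic_to_cds(genomic_pos)
    cds = gene.cds()
    base = alt if gene.strand == "+" else _rc(alt)
    mut_cds = cds[:cds_idx] + base + cds[cds_idx + 1:]
    wt_protein = translate(cds)
    mut_protein = translate(mut_cds)
    codon = cds_idx // 3
    ref_aa = str(Seq(cds[codon * 3:codon * 3 + 3]).translate())
    alt_aa = str(Seq(mut_cds[codon * 3:codon * 3 + 3]).translate())
    if alt_aa == "*":
        cls = "nonsense"
    elif alt_aa == ref_aa:
        cls = "silent"
    else:
        cls = "missense"
    lost = tuple(name for name, _, aa_end in gene.domains if aa_end > len(mut_protein))
    return VariantEffect(effect_class=cls, codon_index=codon + 1, ref_aa=ref_aa,
                         alt_aa=alt_aa, wt_protein_length=len(wt_protein),
                         mut_protein_length=len(mut_protein),
                         lost_domains=lost if cls == "nonsense" else ())


@dataclass(frozen=True)
class IsoformProduct:
    """One splice isoform: event, transcript, translated product."""

    isoform_id: str
    event: tuple
    transcript: str
    protein: str
    termination_aa: int  # length of the translated product
    no_product: bool = False


def splice_isoform(gene: GeneModelCds, event: tuple = ("full",),
                   isoform_id: str | None = None) -> IsoformProduct:
    """Build and translate a declared splice isoform.

    Events: ``("full",)`` — all exons; ``("exon_skip", k)`` — drop transcript
    exon k; ``("intron_retention", k)`` — retain the intron between exons k and
    k+1. Skipping the exon that carries the start codon yields a flagged
    no-product result. Translation stops at the first in-frame stop, so a
    retained intron carrying a stop terminates the product inside the intron.
    """
    kind = event[0]
    if kind == "full":
        transcript = gene.cds()
    elif kind == "exon_skip":
        k = event[1]
        if not (1 <= k <= gene.n_exons):
            raise DataError(f"no exon {k}")
        transcript = "".join(gene.exon_seq(i) for i in range(1, gene.n_exons + 1) if i != k)
        if k == 1:
            return IsoformProduct(isoform_id or f"skip{k}", event, transcript, "", 0, no_product=True)
    elif kind == "intron_retention":
        k = event[1]
        parts = []
        for i in range(1, gene.n_exons + 1):
            parts.append(gene.exon_seq(i))
            if i == k:
                parts.append(gene.intron_seq(k))
        transcript = "".join(parts)
    else:
        raise ValueError(f"unknown event {kind!r}")
    protein = translate(transcript)
    return IsoformProduct(isoform_id or (kind if kind == "full" else f"{kind}{event[1]}"),
                          event, transcript, protein, termination_aa=len(protein))


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # rG:rU written in DNA alphabet


def mir_target_mismatches(mirna: str, site: str, wobble_counts: bool = True) -> int:
    """Count non-Watson-Crick pairs between a miRNA and its target site.

    Both sequences are given 5'->3' (U may be written as T); pairing is
    antiparallel and ungapped, so the sequences must be equal length. G:U
    wobble pairs count as mismatches by default (binary pairing model).
    """
    mi = mirna.upper().replace("U", "T")
    st = site.upper().replace("U", "T")
    if len(mi) != len(st):
        raise DataError("miRNA and site must be equal length (no gapped alignment)")
    if _DNA.search(mi) or _DNA.search(st):
        raise SequenceError("non-nucleotide characters")
    mismatches = 0
    for a, b in zip(mi, reversed(st)):
        if (a, b) in _PAIRS:
            continue
        if (a, b) in _WOBBLE and not wobble_counts:
            continue
        mismatches += 1
    return mismatches
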