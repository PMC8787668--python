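"""Diagnostic marker design: CAPS digests and KASP allele-specific primers.

A CAPS assay exploits a SNP that creates or destroys a restriction site in a
PCR amplicon: the two homozygotes give different digest band patterns and the
heterozygote shows the union of both. A KASP assay genotypes a SNP with two
allele-specific forward primers whose 3'-terminal base is the SNP, each
carrying a universal fluorophore tail (FAM or HEX), plus one common reverse
primer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import DesignError, SequenceError

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: IUPAC recognition string and cut offset.

    ``cut_offset`` is the number of recognition bases 5' of the cut on the
    strand carrying the recognition sequence (DdeI = CTNAG, offset 1: C^TNAG).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if any(b not in IUPAC for b in self.recognition):
            raise SequenceError(f"non-IUPAC character in recognition {self.recognition!r}")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise DesignError("cut_offset outside recognition sequence")


def load_enzyme_table() -> list[RestrictionEnzyme]:
    """The packaged enzyme table (editable TSV: name, recognition, cut offset)."""
    with resources.files("bsakit.data").joinpath("enzymes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [RestrictionEnzyme(r["name"], r["recognition"], int(r["cut_offset"]))
            for _, r in df.iterrows()]


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    if re.search("[^ACGT]", seq):
        raise SequenceError("sequence contains non-ACGT characters")
    return seq


def _iupac_regex(recognition: str) -> re.Pattern:
    pat = "".join(b if len(IUPAC[b]) == 1 else "[" + IUPAC[b] + "]" for b in recognition)
    return re.compile("(?=" + pat + ")")  # lookahead: overlapping matches


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based start positions of recognition sites on either strand.

    Reverse-strand matches are reported by the forward-strand start of the
    matched window and deduplicated (degenerate-palindromic sites like CTNAG
    match identically on both strands).
    """
    seq = _check_seq(seq)
    fwd = {m.start() + 1 for m in _iupac_regex(enzyme.recognition).finditer(seq)}
    rev = {m.start() + 1 for m in _iupac_regex(revcomp(enzyme.recognition)).finditer(seq)}
    return sorted(fwd | rev)


def _cut_positions(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Number of bases 5' of each double-strand cut, deduplicated and sorted."""
    seq = _check_seq(seq)
    L = len(enzyme.recognition)
    cuts = {m.start() + enzyme.cut_offset
            for m in _iupac_regex(enzyme.recognition).finditer(seq)}
    if revcomp(enzyme.recognition) != enzyme.recognition:
        # non-palindromic: reverse-strand sites are distinct, cut offset mirrored
        cuts |= {m.start() + (L - enzyme.cut_offset)
                 for m in _iupac_regex(revcomp(enzyme.recognition)).finditer(seq)}
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths of a complete digest, sorted ascending; lengths sum to len(seq)."""
    seq = _check_seq(seq)
    cuts = _cut_positions(seq, enzyme)
    bounds = [0] + cuts + [len(seq)]
    frags = sorted(b - a for a, b in zip(bounds, bounds[1:]))
    assert sum(frags) == len(seq)
    return frags


@dataclass(frozen=True)
class CapsAssay:
    """Predicted digest banding of one enzyme over a WT/mutant amplicon pair."""

    enzyme: RestrictionEnzyme
    amplicon_wt: str
    amplicon_mut: str
    bands_wt: tuple[int, ...]
    bands_mut: tuple[int, ...]
    bands_het: tuple[int, ...]

    def __post_init__(self) -> None:
        assert sum(self.bands_wt) == len(self.amplicon_wt)
        assert sum(self.bands_mut) == len(self.amplicon_mut)
        assert set(self.bands_het) == set(self.bands_wt) | set(self.bands_mut)

    @property
    def separability(self) -> int:
        """Smallest pairwise difference among heterozygote bands (gel resolvability)."""
        bands = sorted(set(self.bands_het))
        if len(bands) < 2:
            return 0
        return min(b - a for a, b in zip(bands, bands[1:]))


def design_caps(amplicon_wt: str, amplicon_mut: str,
                enzymes: list[RestrictionEnzyme] | None = None) -> list[CapsAssay]:
    """Screen enzymes for allele-differential digestion of an amplicon pair.

    Returns one assay per enzyme whose site count differs between the alleles
    (a gained or lost site), with predicted bands for each homozygote and the
    heterozygote (union of both homozygote band sets). Assays are ranked by
    band separability, best first. An identical pair yields an empty list.
    """
    amplicon_wt = _check_seq(amplicon_wt)
    amplicon_mut = _check_seq(amplicon_mut)
    if len(amplicon_wt) != len(amplicon_mut):
        raise DesignError("amplicons must be equal length")
    if amplicon_wt == amplicon_mut:
        return []
    if enzymes is None:
        enzymes = load_enzyme_table()
    assays = []
    for enz in enzymes:
        if len(find_sites(amplicon_wt, enz)) == len(find_sites(amplicon_mut, enz)):
            continue
        bw = tuple(digest(amplicon_wt, enz))
        bm = tuple(digest(amplicon_mut, enz))
        bh = tuple(sorted(set(bw) | set(bm)))
        assays.append(CapsAssay(enz, amplicon_wt, amplicon_mut, bw, bm, bh))
    return sorted(assays, key=lambda a: -a.separability)


@dataclass(frozen=True)
class KaspAssay:
    """Two tailed allele-specific forward primers plus a common reverse primer."""

    allele1_forward: str
    allele2_forward: str
    common_reverse: str
    snp_alleles: tuple[str, str]

    def __post_init__(self) -> None:
        f1 = self.allele1_forward
        f2 = self.allele2_forward
        assert f1.startswith(FAM_TAIL) and f2.startswith(HEX_TAIL)
        core1, core2 = f1[len(FAM_TAIL):], f2[len(HEX_TAIL):]
        assert core1[:-1] == core2[:-1] and core1[-1] != core2[-1]


def design_kasp(flank_left: str, allele1: str, allele2: str, flank_right: str,
                primer_len: int = 21) -> KaspAssay:
    """Assemble KASP primers around a SNP.

    Each allele-specific forward primer is tail + the last ``primer_len - 1``
    bases of the left flank + the allele base (the SNP sits at the 3' end,
    where a mismatch blocks extension); the common reverse primer is the
    reverse complement of the first ``primer_len`` bases of the right flank.
    """
    flank_left = _check_seq(flank_left)
    flank_right = _check_seq(flank_right)
    allele1, allele2 = allele1.upper(), allele2.upper()
    if allele1 == allele2:
        raise DesignError("alleles identical: not a SNP")
    if len(allele1) != 1 or len(allele2) != 1 or allele1 not in "ACGT" or allele2 not in "ACGT":
        raise SequenceError("alleles must be single bases")
    if len(flank_left) < primer_len - 1:
        raise DesignError(f"left flank shorter than {primer_len - 1} bases")
    if len(flank_right) < primer_len:
        raise DesignError(f"right flank shorter than {primer_len} bases")
    core = flank_left[-(primer_len - 1):]
    return KaspAssay(
        allele1_forward=FAM_TAIL + core + allele1,
        allele2_forward=HEX_TAIL + core + allele2,
        common_reverse=revcomp(flank_right[:primer_len]),
        snp_alleles=(allele1, allele2),
    )
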