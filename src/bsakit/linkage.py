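"""Marker-based fine mapping: recombinant counting, interval delimitation, segregation tests.

Under the dominant model a recombinant is a plant whose marker genotype is
incompatible with the causal genotype its phenotype implies: a normal
(recessive-phenotype) plant must be aa at the causal locus, so AA or Aa at a
fully linked marker marks a recombination; a speltoid plant carries at least
one mutant allele, so only marker aa is incompatible. Heterozygous markers in
speltoid plants are compatible with A_ and therefore never scored as
recombinant — the dominant-model asymmetry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .simdata import NORMAL, SPELTOID, F2Individual

logger = logging.getLogger("bsakit")

MISSING = "missing"


@dataclass(frozen=True)
class Marker:
    id: str
    chrom: str
    pos: int


def genotype_markers(population: list[F2Individual], markers: list[Marker]) -> pd.DataFrame:
    """Score every individual at every marker; one row per plant.

    Columns: phenotype plus one genotype column per marker id.
    """
    code = {0: "aa", 1: "Aa", 2: "AA"}
    rows = []
    for ind in population:
        row = {"individual": ind.id, "phenotype": ind.phenotype}
        for m in markers:
            row[m.id] = code[int(ind.dosage_at(m.chrom, m.pos)[0])]
        rows.append(row)
    return pd.DataFrame(rows).set_index("individual")


def count_recombinants(table: pd.DataFrame, marker_id: str) -> int:
    """Count plants whose marker genotype contradicts their phenotype-implied causal genotype."""
    if marker_id not in table.columns:
        raise KeyError(f"unknown marker {marker_id!r}")
    geno = table[marker_id]
    scored = geno != MISSING
    if not scored.any():
        warnings.warn(f"all genotypes missing at marker {marker_id}")
        return 0
    pheno = table["phenotype"]
    rec = ((pheno == NORMAL) & geno.isin(["AA", "Aa"])) | ((pheno == SPELTOID) & (geno == "aa"))
    return int((rec & scored).sum())


def delimit_interval(table: pd.DataFrame, markers: list[Marker],
                     chrom_length: int | None = None
                     ) -> tuple[Marker | None, Marker | None, tuple[int, int]]:
    """Delimit the candidate interval by flanking markers around the recombinant minimum.

    The marker(s) with the fewest recombinants anchor the interval; the bounds
    are the nearest markers on each side with strictly more recombinants (or
    the chromosome ends). Ties at the minimum widen the anchor set, hence the
    interval — the conservative choice. Markers must share one chromosome and
    are sorted by position internally.
    """
    if len(markers) < 3:
        raise ValueError("need at least 3 markers on the target chromosome")
    chroms = {m.chrom for m in markers}
    if len(chroms) != 1:
        raise ValueError("markers must lie on a single chromosome")
    ms = sorted(markers, key=lambda m: m.pos)
    counts = np.array([count_recombinants(table, m.id) for m in ms])
    cmin = counts.min()
    if (counts == cmin).all():
        warnings.warn("all markers have equal recombinant counts; whole-chromosome interval")
        return None, None, (1, chrom_length or ms[-1].pos)
    tied = np.flatnonzero(counts == cmin)
    left_anchor, right_anchor = tied.min(), tied.max()
    left = next((i for i in range(left_anchor - 1, -1, -1) if counts[i] > cmin), None)
    right = next((i for i in range(right_anchor + 1, len(ms)) if counts[i] > cmin), None)
    left_marker = ms[left] if left is not None else None
    right_marker = ms[right] if right is not None else None
    lo = left_marker.pos if left_marker else 1
    hi = right_marker.pos if right_marker else (chrom_length or ms[-1].pos)
    logger.info("interval anchored at %s (%d recombinants): %s-%s",
                ms[left_anchor].id, cmin, lo, hi)
    return left_marker, right_marker, (lo, hi)


@dataclass(frozen=True)
class SegregationTestResult:
    observed: tuple[int, int]
    expected_ratio: tuple[float, float]
    chi2: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not (0.0 <= self.p_value <= 1.0):
            raise DataError("invalid test result")


def chi_square_segregation(n_dom: int, n_rec: int,
                           ratio: tuple[float, float] = (3, 1),
                           yates: bool = False) -> SegregationTestResult:
    """Pearson chi-square goodness of fit of observed phenotype counts to a ratio."""
    if n_dom < 0 or n_rec < 0:
        raise DataError("negative phenotype counts")
    n = n_dom + n_rec
    if n == 0:
        raise DataError("no plants scored")
    obs = np.array([n_dom, n_rec], dtype=float)
    exp = np.array(ratio, dtype=float) / sum(ratio) * n
    if yates:
        chi2 = float((((np.abs(obs - exp) - 0.5) ** 2) / exp).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = stats.chisquare(obs, exp)
        chi2, p = float(chi2), float(p)
    return SegregationTestResult(observed=(n_dom, n_rec), expected_ratio=tuple(ratio),
                                 chi2=chi2, df=len(obs) - 1, p_value=p)
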