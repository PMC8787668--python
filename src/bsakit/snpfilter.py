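"""Parental genotype calling and the two SNP quality filters.

A locus survives when (1) both parents were sequenced to at least ``min_depth``
and (2) the two inbred parents carry different homozygous genotypes. An
accounting record tracks where every input locus went; its counts always sum
back to the input total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger("bsakit")

# genotype call codes
HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
AMBIGUOUS = "ambiguous"
NO_CALL = "no_call"


@dataclass(frozen=True)
class FilterAccounting:
    """Where each input locus ended up; counts are conserved by construction."""

    total: int
    removed_low_depth: int
    removed_monomorphic: int
    retained: int

    def __post_init__(self) -> None:
        if min(self.total, self.removed_low_depth, self.removed_monomorphic, self.retained) < 0:
            raise DataError("accounting counts must be non-negative")
        if self.total != self.removed_low_depth + self.removed_monomorphic + self.retained:
            raise DataError("accounting counts do not sum to total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "total": self.total,
            "removed_low_depth": self.removed_low_depth,
            "removed_monomorphic": self.removed_monomorphic,
            "retained": self.retained,
        }])


def call_parent_genotype(ref_depth, alt_depth, purity: float = 0.9) -> np.ndarray:
    """Call a parent genotype from per-allele read counts.

    Homozygous when the major allele carries at least ``purity`` of the reads
    (inbred parents should be homozygous; anything else is ambiguous), no-call
    at zero depth. Vectorized; scalars give a length-1 array.
    """
    ref = np.atleast_1d(np.asarray(ref_depth, dtype=np.int64))
    alt = np.atleast_1d(np.asarray(alt_depth, dtype=np.int64))
    if (ref < 0).any() or (alt < 0).any():
        raise DataError("negative allele depth")
    total = ref + alt
    out = np.full(ref.shape, AMBIGUOUS, dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_ref = np.where(total > 0, ref / np.maximum(total, 1), 0.0)
        frac_alt = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    out[frac_ref >= purity] = HOM_REF
    out[frac_alt >= purity] = HOM_ALT
    out[total == 0] = NO_CALL
    return out


def filter_by_parent_depth(table: pd.DataFrame, min_depth: int = 4,
                           mode: str = "either") -> tuple[pd.DataFrame, int]:
    """Drop loci with parental sequencing depth below ``min_depth``.

    ``mode='either'`` (default) removes a locus when EITHER parent is shallow —
    a cross-informative genotype cannot be trusted if one parent is under-covered.
    ``mode='both'`` requires both parents shallow. Order is preserved.
    """
    dp_a = table["pA_ref"] + table["pA_alt"]
    dp_b = table["pB_ref"] + table["pB_alt"]
    if (dp_a < 0).any() or (dp_b < 0).any():
        raise DataError("negative parental depth")
    if mode == "either":
        low = (dp_a < min_depth) | (dp_b < min_depth)
    elif mode == "both":
        low = (dp_a < min_depth) & (dp_b < min_depth)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    kept = table.loc[~low]
    return kept, int(low.sum())


def filter_monomorphic(table: pd.DataFrame, purity: float = 0.9) -> tuple[pd.DataFrame, int]:
    """Drop loci where the parents are not confidently opposite homozygotes.

    Same-genotype parents carry no mapping information; ambiguous or no-call
    parents (apparent heterozygosity in an inbred line signals an artifact)
    are discarded with them.
    """
    call_a = call_parent_genotype(table["pA_ref"], table["pA_alt"], purity)
    call_b = call_parent_genotype(table["pB_ref"], table["pB_alt"], purity)
    hom = {HOM_REF, HOM_ALT}
    informative = (
        np.isin(call_a, list(hom)) & np.isin(call_b, list(hom)) & (call_a != call_b)
    )
    kept = table.loc[informative]
    return kept, int((~informative).sum())


def run_filters(table: pd.DataFrame, min_depth: int = 4, purity: float = 0.9,
                depth_mode: str = "either") -> tuple[pd.DataFrame, FilterAccounting]:
    """Apply the depth filter then the monomorphism filter, with accounting."""
    total = len(table)
    after_depth, n_low = filter_by_parent_depth(table, min_depth=min_depth, mode=depth_mode)
    kept, n_mono = filter_monomorphic(after_depth, purity=purity)
    acc = FilterAccounting(total=total, removed_low_depth=n_low,
                           removed_monomorphic=n_mono, retained=len(kept))
    logger.info("filters: %d total, %d low-depth, %d monomorphic, %d retained",
                acc.total, acc.removed_low_depth, acc.removed_monomorphic, acc.retained)
    return kept, acc
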