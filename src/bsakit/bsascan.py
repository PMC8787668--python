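"""Bulked-segregant scan: SNP-index, dSNP-index, LOESS smoothing, candidate regions.

The SNP-index of a bulk at a locus is the fraction of its reads carrying the
mutant-parent allele; the dSNP-index is the difference between the two bulks'
indices. Under a dominant causal allele with phenotype-pure 50-plant bulks,
the dSNP-index expectation is 2/3 at the causal locus (speltoid bulk AA:Aa in
1:2, allele frequency 2/3; normal bulk all aa) and 0 at unlinked loci. A
LOESS fit of |dSNP-index| along each chromosome suppresses locus-level noise;
candidate regions are runs of loci whose fitted value reaches a genome-wide
quantile threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("bsakit")


def snp_index(mut_allele_reads, total_reads) -> np.ndarray:
    """Fraction of bulk reads carrying the mutant-parent allele; NaN at zero depth."""
    alt = np.atleast_1d(np.asarray(mut_allele_reads, dtype=float))
    dp = np.atleast_1d(np.asarray(total_reads, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(dp > 0, alt / np.maximum(dp, 1e-300), np.nan)
    return idx


def delta_snp_index(table: pd.DataFrame) -> pd.DataFrame:
    """Per-locus SNP-index track for both bulks and their difference.

    Loci where either bulk has zero depth get NaN delta and are excluded from
    smoothing (but retained in the output).
    """
    track = table[["chrom", "pos"]].copy()
    track["index_mut"] = snp_index(table["bulk_mut_alt"].to_numpy(), table["bulk_mut_dp"].to_numpy())
    track["index_wt"] = snp_index(table["bulk_wt_alt"].to_numpy(), table["bulk_wt_dp"].to_numpy())
    track["delta"] = track["index_mut"] - track["index_wt"]
    track["abs_delta"] = track["delta"].abs()
    return track


def loess_fit(positions, values, span: float = 0.1, degree: int = 1,
              iterations: int = 2) -> np.ndarray:
    """Classic LOESS: tricube-weighted local polynomial fit at each observed position.

    ``span`` is the fraction of points in each local window, ``degree`` the
    local polynomial degree, ``iterations`` the number of robustness passes
    (bisquare reweighting of residuals). Positions must be sorted ascending.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("positions and values must have equal length")
    if np.any(np.diff(x) < 0):
        raise ValueError("positions must be sorted ascending")
    k = max(degree + 2, 3, int(np.ceil(span * n)))
    if n < k:
        warnings.warn(f"chromosome has {n} points, fewer than the LOESS window {k}; skipped")
        return np.full(n, np.nan)

    robustness = np.ones(n)
    fitted = np.empty(n)
    for it in range(iterations + 1):
        for i in range(n):
            # contiguous window of the k nearest points (x is sorted)
            lo = min(max(0, i - k // 2), n - k)
            while lo > 0 and x[i] - x[lo - 1] < x[lo + k - 1] - x[i]:
                lo -= 1
            while lo + k < n and x[lo + k] - x[i] < x[i] - x[lo]:
                lo += 1
            hi = lo + k
            xi = x[lo:hi]
            yi = y[lo:hi]
            d = np.abs(xi - x[i])
            dmax = d.max()
            w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
            w = np.clip(w, 0.0, None) * robustness[lo:hi]
            if w.sum() <= 0:
                w = np.ones_like(d)
            # weighted polynomial fit centred on x[i] for conditioning
            X = np.vander(xi - x[i], degree + 1, increasing=True)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], yi * sw, rcond=None)
            fitted[i] = beta[0]
        if it < iterations:
            resid = y - fitted
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            robustness = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return fitted


def fit_track(track: pd.DataFrame, span: float = 0.1, degree: int = 1,
              iterations: int = 2) -> pd.DataFrame:
    """LOESS-fit |dSNP-index| per chromosome; fitted values clipped to [0, 1].

    Smoothing never crosses a chromosome boundary. Loci with missing delta are
    excluded from the fit and carry NaN fitted values.
    """
    out = track.copy()
    out["fitted"] = np.nan
    for chrom, grp in track.groupby("chrom", sort=False):
        ok = grp["abs_delta"].notna()
        sub = grp.loc[ok].sort_values("pos")
        if len(sub) == 0:
            continue
        fit = loess_fit(sub["pos"].to_numpy(), sub["abs_delta"].to_numpy(),
                        span=span, degree=degree, iterations=iterations)
        out.loc[sub.index, "fitted"] = np.clip(fit, 0.0, 1.0)
    return out


@dataclass(frozen=True)
class CandidateRegion:
    """A run of consecutive loci whose fitted |dSNP-index| reaches the threshold."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    peak_pos: int
    peak_fitted: float
    threshold: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_pos <= self.end):
            raise ValueError("peak must lie inside the region")


def call_candidate_regions(track: pd.DataFrame, quantile: float = 0.99) -> list[CandidateRegion]:
    """Threshold the fitted track at a genome-wide quantile and emit maximal runs.

    An all-tied fitted track cannot be thresholded meaningfully; in that
    degenerate case each chromosome is returned whole, flagged, with a warning.
    """
    fitted = track["fitted"].to_numpy(dtype=float)
    ok = np.isfinite(fitted)
    if not ok.any():
        return []
    threshold = float(np.quantile(fitted[ok], quantile))
    if np.nanmax(fitted[ok]) == np.nanmin(fitted[ok]):
        warnings.warn("all fitted values tied; returning degenerate whole-chromosome regions")
        regions = []
        for chrom, grp in track.groupby("chrom", sort=False):
            sub = grp.loc[grp["fitted"].notna()]
            if len(sub) == 0:
                continue
            regions.append(CandidateRegion(
                chrom=str(chrom), start=int(sub["pos"].min()), end=int(sub["pos"].max()),
                peak_pos=int(sub["pos"].min()), peak_fitted=float(sub["fitted"].iloc[0]),
                threshold=threshold, degenerate=True))
        return regions

    regions: list[CandidateRegion] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        sub = grp.loc[grp["fitted"].notna()].sort_values("pos")
        above = (sub["fitted"] >= threshold).to_numpy()
        pos = sub["pos"].to_numpy()
        fit = sub["fitted"].to_numpy()
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            peak = int(np.argmax(fit[seg])) + i
            regions.append(CandidateRegion(
                chrom=str(chrom), start=int(pos[i]), end=int(pos[j]),
                peak_pos=int(pos[peak]), peak_fitted=float(fit[peak]),
                threshold=threshold))
            i = j + 1
    logger.info("candidate regions: %d at threshold %.4f", len(regions), threshold)
    return regions


def scan(table: pd.DataFrame, span: float = 0.1, degree: int = 1,
         iterations: int = 2, quantile: float = 0.99
         ) -> tuple[pd.DataFrame, list[CandidateRegion]]:
    """Full scan: dSNP-index track, LOESS fit, candidate regions."""
    track = fit_track(delta_snp_index(table), span=span, degree=degree, iterations=iterations)
    return track, call_candidate_regions(track, quantile=quantile)
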