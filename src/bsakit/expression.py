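"""Expression quantification and differential-expression calling.

Two quantification routes: relative qPCR expression by the 2^-ddCT method
(doubling per cycle, normalized to a reference gene and a calibrator sample)
and FPKM from read counts. Differential expression uses a Welch two-sample
test on log2(FPKM + 1) with Benjamini-Hochberg adjustment; a gene is called
differentially expressed when its expression changes at least twofold and its
adjusted FDR is below 0.05 (defaults, configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

logger = logging.getLogger("bsakit")


@dataclass(frozen=True)
class QpcrResult:
    relative_expression: float
    sd: float
    ddct: float


def _ct_stats(target_cts, reference_cts) -> tuple[float, float]:
    t = np.asarray(target_cts, dtype=float)
    r = np.asarray(reference_cts, dtype=float)
    if len(t) == 0 or len(r) == 0:
        raise DataError("missing target or reference CT values")
    if (t <= 0).any() or (r <= 0).any():
        raise DataError("CT values must be positive")
    dct = t.mean() - r.mean()
    var = t.var(ddof=1) / len(t) + r.var(ddof=1) / len(r) if len(t) > 1 and len(r) > 1 else 0.0
    return dct, var


def delta_delta_ct(sample_target_cts, sample_reference_cts,
                   calibrator_target_cts, calibrator_reference_cts) -> QpcrResult:
    """Relative expression by 2^-ddCT with technical replicates.

    dCT = mean(target CT) - mean(reference CT) per condition; ddCT is the
    sample dCT minus the calibrator dCT; relative expression is 2^-ddCT.
    Technical-replicate SD is propagated (delta method) to an SD of the
    relative expression.
    """
    dct_s, var_s = _ct_stats(sample_target_cts, sample_reference_cts)
    dct_c, var_c = _ct_stats(calibrator_target_cts, calibrator_reference_cts)
    ddct = dct_s - dct_c
    rel = float(2.0 ** (-ddct))
    sd = float(rel * np.log(2) * np.sqrt(var_s + var_c))
    return QpcrResult(relative_expression=rel, sd=sd, ddct=float(ddct))


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         totals: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of exon model per million mapped fragments.

    FPKM[g, s] = count[g, s] * 1e9 / (length[g] * total[s]); totals default to
    the per-sample column sums.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise DataError("gene lengths must be positive and present for all genes")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise DataError("per-sample totals must be positive")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(counts: pd.DataFrame, lengths: pd.Series, groups: dict[str, list[str]],
              fc_threshold: float = 2.0, q_threshold: float = 0.05,
              min_mean_fpkm: float = 1.0, pseudocount: float = 1.0) -> pd.DataFrame:
    """Two-group differential expression with the twofold + FDR rule.

    ``groups`` maps the two group names to their sample columns (>= 2
    replicates each). Per gene: Welch t on log2(FPKM + pseudocount), BH
    adjustment across tested genes, DEG iff |log2FC| >= log2(fc_threshold)
    and q < q_threshold. Genes whose mean FPKM stays below ``min_mean_fpkm``
    in both groups are excluded from testing (tested=False).

    log2FC is group2 minus group1 in the order the mapping iterates, so
    swapping the groups flips its sign and leaves q unchanged.
    """
    if len(groups) != 2:
        raise DataError("exactly two groups required")
    (name_a, cols_a), (name_b, cols_b) = groups.items()
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DataError("each group needs at least 2 replicates")
    f = fpkm(counts[list(cols_a) + list(cols_b)], lengths)
    log_a = np.log2(f[list(cols_a)].to_numpy() + pseudocount)
    log_b = np.log2(f[list(cols_b)].to_numpy() + pseudocount)
    log2fc = log_b.mean(axis=1) - log_a.mean(axis=1)
    expressed = (f[list(cols_a)].mean(axis=1) >= min_mean_fpkm) | \
                (f[list(cols_b)].mean(axis=1) >= min_mean_fpkm)
    tested = expressed.to_numpy()

    p = np.full(len(f), np.nan)
    if tested.any():
        res = stats.ttest_ind(log_b[tested], log_a[tested], axis=1, equal_var=False)
        pt = np.asarray(res.pvalue, dtype=float)
        pt = np.where(np.isnan(pt), 1.0, pt)  # zero-variance identical groups
        p[tested] = pt
    q = np.full(len(f), np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    out = pd.DataFrame({
        "log2fc": log2fc,
        "p_value": p,
        "q_value": q,
        "tested": tested,
    }, index=f.index)
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out["is_deg"] = (
        out["tested"]
        & (out["log2fc"].abs() >= np.log2(fc_threshold))
        & (out["q_value"] < q_threshold)
    )
    logger.info("DEG calling (%s vs %s): %d tested, %d DEGs",
                name_b, name_a, int(tested.sum()), int(out["is_deg"].sum()))
    return out
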