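"""Peak-to-gene target assignment and naive k-mer motif enrichment.

Each binding peak is anchored at its midpoint and assigned to the gene with
the smallest absolute signed TSS distance (negative = upstream, strand-aware).
Peaks within -10 kb/+5 kb of a TSS are 'genic-window' peaks; peaks within
-2 kb/+500 bp define putative direct targets. Enriched k-mers are ranked
against a per-sequence dinucleotide-shuffled background — a deliberately
simple, fully self-contained alternative to PWM motif discovery.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .errors import DataError, SequenceError

logger = logging.getLogger("bsakit")

GENIC_WINDOW = (-10_000, 5_000)
TARGET_WINDOW = (-2_000, 500)

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def peak_anchor(start: int, end: int) -> int:
    """Midpoint anchor of a BED interval (0-based half-open), as a 1-based position."""
    if start >= end:
        raise DataError("peak start must be < end")
    return (start + end) // 2 + 1


def signed_tss_distance(anchor: int, tss: int, strand: str) -> int:
    """Signed distance of an anchor to a TSS; negative means upstream of the gene."""
    if strand == "+":
        return anchor - tss
    if strand == "-":
        return tss - anchor
    raise DataError(f"bad strand {strand!r}")


def assign_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                 genic_window: tuple[int, int] = GENIC_WINDOW,
                 target_window: tuple[int, int] = TARGET_WINDOW) -> pd.DataFrame:
    """Assign every peak to its nearest-TSS gene and set the window flags.

    ``peaks``: columns chrom, start, end (BED convention) and name.
    ``genes``: columns gene_id, chrom, tss (1-based), strand.
    Ties at equal |distance| resolve to the lexicographically smaller gene_id
    (logged). Peaks on chromosomes without genes get a null assignment.
    """
    if len(genes) == 0:
        raise DataError("empty gene set")
    rows = []
    by_chrom = {c: g.sort_values(["tss", "gene_id"]).reset_index(drop=True)
                for c, g in genes.groupby("chrom")}
    for _, p in peaks.iterrows():
        anchor = peak_anchor(int(p["start"]), int(p["end"]))
        g = by_chrom.get(p["chrom"])
        if g is None:
            rows.append({"peak": p["name"], "gene_id": None, "distance": np.nan,
                         "in_genic_window": False, "is_putative_target": False})
            continue
        tss = g["tss"].to_numpy()
        i = int(np.searchsorted(tss, anchor))
        cand = [j for j in (i - 1, i, i + 1) if 0 <= j < len(g)]
        dists = {j: signed_tss_distance(anchor, int(tss[j]), g.loc[j, "strand"]) for j in cand}
        best = min(cand, key=lambda j: (abs(dists[j]), g.loc[j, "gene_id"]))
        tie = [j for j in cand if abs(dists[j]) == abs(dists[best])]
        if len(tie) > 1:
            logger.info("peak %s: |distance| tie among %s; assigned to %s",
                        p["name"], [g.loc[j, "gene_id"] for j in tie], g.loc[best, "gene_id"])
        d = dists[best]
        rows.append({
            "peak": p["name"],
            "gene_id": g.loc[best, "gene_id"],
            "distance": d,
            "in_genic_window": genic_window[0] <= d <= genic_window[1],
            "is_putative_target": target_window[0] <= d <= target_window[1],
        })
    out = pd.DataFrame(rows)
    # window flags must agree with distances on every assignment
    ok = out["distance"].notna()
    assert (out.loc[ok, "in_genic_window"] ==
            out.loc[ok, "distance"].between(*genic_window)).all()
    assert (out.loc[ok, "is_putative_target"] ==
            out.loc[ok, "distance"].between(*target_window)).all()
    return out


def putative_targets(assignments: pd.DataFrame) -> set[str]:
    """Gene ids bound within the putative-target window."""
    return set(assignments.loc[assignments["is_putative_target"], "gene_id"])


def intersect_degs(targets: set[str], degs: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Split bound target genes by differential-expression direction.

    ``degs`` is the call_degs output (indexed by gene id). Returns
    (downregulated targets, upregulated targets).
    """
    de = degs.loc[degs["is_deg"]]
    down = set(de.loc[de["direction"] == "down"].index) & targets
    up = set(de.loc[de["direction"] == "up"].index) & targets
    logger.info("target-DEG intersection: %d down, %d up", len(down), len(up))
    return down, up


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide composition.

    Altschul-Erickson: treat the sequence as an Eulerian walk on the
    first-order transition multigraph, draw a random last-exit edge ordering
    that keeps the walk connected to the terminal vertex, and re-walk.
    """
    s = seq.upper()
    if len(s) <= 2:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges.keys() | {s[-1]})
    last = s[-1]
    # choose a random last edge for each non-terminal vertex such that the
    # last-edge graph is connected to the terminal vertex
    for _ in range(100):
        lasts = {v: edges[v][int(rng.integers(len(edges[v])))] for v in edges if v != last}
        ok = True
        for v in lasts:
            seen = {v}
            w = v
            while w != last:
                w = lasts.get(w)
                if w is None or w in seen:
                    ok = False
                    break
                seen.add(w)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - vanishingly unlikely for DNA alphabets
        return s
    shuffled_edges = {}
    for v, out in edges.items():
        rest = list(out)
        if v != last:
            rest.remove(lasts[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(lasts[v])
        shuffled_edges[v] = rest
    walk = [s[0]]
    ptr = {v: 0 for v in shuffled_edges}
    v = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled_edges[v][ptr[v]]
        ptr[v] += 1
        walk.append(nxt)
        v = nxt
    out = "".join(walk)
    assert sorted(out) == sorted(s)
    return out


def _count_kmers(seqs, k: int, counter: dict[str, int]) -> None:
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            if "N" in kmer:
                continue
            canon = min(kmer, _revcomp(kmer))
            counter[canon] = counter.get(canon, 0) + 1


def kmer_enrichment(peak_seqs: list[str], k: int = 5, n_shuffles: int = 10,
                    seed: int = 0) -> pd.DataFrame:
    """Rank k-mers by enrichment over a dinucleotide-shuffled background.

    K-mers are collapsed with their reverse complements (lexicographically
    smaller representative). Score = log2((c_fg + 1) / (c_bg / n_shuffles + 1));
    rows sorted by score descending, ties broken lexicographically.
    """
    if any(len(s) < k for s in peak_seqs):
        raise SequenceError(f"all sequences must be at least {k} bases")
    for s in peak_seqs:
        if set(s.upper()) - set("ACGTN"):
            raise SequenceError("non-nucleotide characters in peak sequence")
    rng = derive_rng(seed, "kmer_background")
    fg: dict[str, int] = {}
    _count_kmers(peak_seqs, k, fg)
    bg: dict[str, int] = {}
    for s in peak_seqs:
        for _ in range(n_shuffles):
            _count_kmers([dinucleotide_shuffle(s, rng)], k, bg)
    kmers = sorted(set(fg) | set(bg))
    df = pd.DataFrame({
        "kmer": kmers,
        "fg_count": [fg.get(m, 0) for m in kmers],
        "bg_count": [bg.get(m, 0) for m in kmers],
    })
    df["score"] = np.log2((df["fg_count"] + 1) / (df["bg_count"] / n_shuffles + 1))
    df = df.sort_values(["score", "kmer"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
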