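"""Interval-set algebra for replicate consensus, overlap filters and annotation.

Consensus is defined at base resolution: a base belongs to the k-of-n
consensus when at least k replicate peak sets cover it.  Exclusivity uses
the strictest overlap rule (a single shared base disqualifies), while the
enhancer intersections keep only pieces longer than a minimum length —
the two rules are deliberately distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, IntervalSet, TSSAnnotation


@dataclass(frozen=True)
class ConsensusSpec:
    """Minimum replicate support k out of n."""

    k: int
    n: int

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.n):
            raise ValueError(f"require 1 <= k <= n, got k={self.k}, n={self.n}")


def _coverage_runs(spans: np.ndarray, min_cov: int) -> list[tuple[int, int]]:
    """Maximal runs of bases covered by >= min_cov of the given spans."""
    if spans.size == 0:
        return []
    events = np.concatenate(
        [
            np.stack([spans[:, 0], np.ones(len(spans), dtype=np.int64)], axis=1),
            np.stack([spans[:, 1], -np.ones(len(spans), dtype=np.int64)], axis=1),
        ]
    )
    order = np.lexsort((events[:, 1], events[:, 0]))
    events = events[order]
    runs: list[tuple[int, int]] = []
    cov = 0
    run_start: int | None = None
    for pos, delta in events:
        new_cov = cov + delta
        if cov < min_cov <= new_cov:
            run_start = int(pos)
        elif new_cov < min_cov <= cov:
            if run_start is not None and int(pos) > run_start:
                runs.append((run_start, int(pos)))
            run_start = None
        cov = new_cov
    # merge book-ended runs produced by coincident events
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def consensus_peaks(replicates: Sequence[IntervalSet], k: int) -> IntervalSet:
    """Bases covered by at least k of n replicate peak sets, as maximal intervals.

    Each replicate is merged internally first so a replicate contributes at
    most one unit of coverage per base.  k=1 gives the merged union; k=n the
    n-way intersection; covered bases are antitone in k.
    """
    n = len(replicates)
    ConsensusSpec(k, n)  # validates 1 <= k <= n
    per_rep = [r.merge().by_chrom() for r in replicates]
    chroms = sorted({c for rep in per_rep for c in rep})
    out: list[GenomicInterval] = []
    for chrom in chroms:
        spans = np.concatenate(
            [rep.get(chrom, np.empty((0, 2), dtype=np.int64)) for rep in per_rep]
        )
        for s, e in _coverage_runs(spans, k):
            out.append(GenomicInterval(chrom, s, e))
    return IntervalSet(out, label=f"consensus_k{k}")


def intersect_min_overlap(
    a: IntervalSet, b: IntervalSet, min_len: int = 50
) -> IntervalSet:
    """Base-wise intersection of two merged sets, keeping pieces longer than min_len.

    The boundary is strict: a piece of exactly ``min_len`` bases is dropped.
    The result is a base-wise subset of both inputs.
    """
    am, bm = a.merge().by_chrom(), b.merge().by_chrom()
    out: list[GenomicInterval] = []
    for chrom in sorted(set(am) & set(bm)):
        sa, sb = am[chrom], bm[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i, 0], sb[j, 0])
            hi = min(sa[i, 1], sb[j, 1])
            if hi - lo > min_len:
                out.append(GenomicInterval(chrom, int(lo), int(hi)))
            if sa[i, 1] <= sb[j, 1]:
                i += 1
            else:
                j += 1
    return IntervalSet(out, label=f"{a.label}&{b.label}")


def exclusive_peaks(
    triple: Mapping[str, IntervalSet], focal: str
) -> IntervalSet:
    """Members of the focal comparison overlapping no peak of the other two.

    A single shared base disqualifies a focal peak.  The result is a subset
    (member-wise) of the focal input.
    """
    if focal not in triple:
        raise KeyError(f"focal label {focal!r} not among {sorted(triple)}")
    others: list[np.ndarray | dict] = [
        triple[lab].merge().by_chrom() for lab in triple if lab != focal
    ]
    kept: list[GenomicInterval] = []
    for iv in triple[focal].sort():
        clash = False
        for other in others:
            spans = other.get(iv.chrom)
            if spans is None or not len(spans):
                continue
            j = int(np.searchsorted(spans[:, 0], iv.end))
            # spans[:j] start before iv.end; overlap iff any such span ends after iv.start
            if j > 0 and spans[:j, 1].max() > iv.start:
                clash = True
                break
        if not clash:
            kept.append(iv)
    return IntervalSet(kept, label=f"{focal}_exclusive")


# ---------------------------------------------------------------------------
# Annotation


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene structure for feature classification."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def tss(self) -> int:
        return self.start if self.strand != "-" else self.end - 1


def feature_distribution(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    promoter_flank: int = 2000,
) -> pd.DataFrame:
    """Classify each peak midpoint as promoter, exon, intron or distal.

    Precedence is promoter > exon > intron > distal; the promoter is the TSS
    +/- ``promoter_flank`` window.  Returns (category, count, proportion)
    with proportions summing to 1.
    """
    if not len(peaks):
        raise ValueError("empty peak set")
    categories = ["promoter", "exon", "intron", "distal"]
    counts = dict.fromkeys(categories, 0)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for iv in peaks:
        mid = iv.midpoint
        assigned = "distal"
        for g in by_chrom.get(iv.chrom, []):
            if abs(mid - g.tss) <= promoter_flank:
                assigned = "promoter"
                break
            if g.start <= mid < g.end:
                in_exon = any(s <= mid < e for s, e in g.exons)
                cand = "exon" if in_exon else "intron"
                if categories.index(cand) < categories.index(assigned):
                    assigned = cand
        counts[assigned] += 1
    total = len(peaks)
    return pd.DataFrame(
        {
            "category": categories,
            "count": [counts[c] for c in categories],
            "proportion": [counts[c] / total for c in categories],
        }
    )


def nearest_gene(peaks: IntervalSet, tss: TSSAnnotation) -> pd.DataFrame:
    """Nearest-TSS assignment per peak.

    Distance is measured from the peak midpoint to each TSS; ties go to the
    lower-coordinate TSS.  The signed distance is oriented by gene strand
    (positive = midpoint downstream of the TSS).  Peaks on chromosomes with
    no TSS are reported unassigned (gene_id NA).
    """
    by_chrom = tss.by_chrom()
    arrays = {
        c: (np.array([r.tss for r in recs]), recs) for c, recs in by_chrom.items()
    }
    rows = []
    for iv in peaks:
        mid = iv.midpoint
        entry = arrays.get(iv.chrom)
        if entry is None:
            rows.append(
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                 "gene_id": pd.NA, "distance": pd.NA}
            )
            continue
        positions, recs = entry
        dist = np.abs(positions - mid)
        best = int(np.lexsort((positions, dist))[0])
        rec = recs[best]
        signed = mid - rec.tss if rec.strand != "-" else rec.tss - mid
        rows.append(
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "gene_id": rec.gene_id, "distance": int(signed)}
        )
    return pd.DataFrame(rows)
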