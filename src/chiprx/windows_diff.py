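"""Sliding-window negative-binomial differential testing and coverage tracks.

The differential scan counts fragment midpoints in windows tiling each
chromosome, estimates a per-window negative-binomial dispersion by binned
method of moments, and compares the two groups with a likelihood-ratio test
of equal NB means (shared dispersion, chi-square with 1 df).  Significant
windows of the same direction are merged into differential regions.

Inputs are assumed pre-scaled (spike-in downsampling upstream); no further
library-size normalisation is applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GenomicInterval, TSSAnnotation

logger = logging.getLogger("chiprx")

DISPERSION_FLOOR = 1e-4


@dataclass(frozen=True)
class WindowGrid:
    """Windows of size ``window`` every ``step`` bp, tiling each chromosome from 0."""

    window: int
    step: int
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window size must be positive")
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")

    def n_windows(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return max(1, -(-length // self.step))  # ceil

    def window_frame(self) -> pd.DataFrame:
        """All windows as (chrom, start, end) in grid order."""
        rows = []
        for chrom in self.chrom_lengths:
            starts = np.arange(self.n_windows(chrom)) * self.step
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + self.window}
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class DifferentialRegion:
    """Merged run of significant windows with a common direction."""

    chrom: str
    start: int
    end: int
    log2fc: float
    pvalue: float
    padj: float
    direction: str  # "up" iff log2fc > 0

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.direction)


# ---------------------------------------------------------------------------
# Fragment -> point assignment


def extend_fragments(frags: pd.DataFrame, fragment_length: int = 300) -> pd.DataFrame:
    """Resolve each record to a single assignment point (fragment midpoint).

    Stranded records are treated as reads and extended to ``fragment_length``
    from their 5' end; the midpoint of the extended fragment is the point.
    Unstranded records (strand '.') are taken as complete fragments and
    contribute their own midpoint; the extension length is ignored for them.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    half = fragment_length // 2
    strand = (
        frags["strand"] if "strand" in frags.columns else pd.Series(".", index=frags.index)
    )
    pos = (frags["start"].to_numpy() + frags["end"].to_numpy()) // 2
    plus = (strand == "+").to_numpy()
    minus = (strand == "-").to_numpy()
    pos = np.where(plus, frags["start"].to_numpy() + half, pos)
    pos = np.where(minus, frags["end"].to_numpy() - half, pos)
    out = pd.DataFrame(
        {
            "chrom": frags["chrom"].to_numpy(),
            "pos": np.maximum(pos, 0).astype(np.int64),
        }
    )
    if "sample" in frags.columns:
        out["sample"] = frags["sample"].to_numpy()
    return out


def count_windows(
    points: pd.DataFrame, grid: WindowGrid, samples: Sequence[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Count assignment points per (window, sample).

    A point increments every window whose half-open span contains it; with
    step == window each point is counted exactly once.  Points at or beyond
    the chromosome length are assigned to the last window with a warning.

    Returns ``(window_frame, counts)`` where counts is (n_windows, n_samples)
    in the order of ``samples`` (default: sorted unique sample labels).
    """
    if samples is None:
        samples = sorted(points["sample"].unique()) if len(points) else []
    sample_index = {s: j for j, s in enumerate(samples)}
    windows = grid.window_frame()
    offsets: dict[str, int] = {}
    off = 0
    for chrom in grid.chrom_lengths:
        offsets[chrom] = off
        off += grid.n_windows(chrom)
    counts = np.zeros((len(windows), len(samples)), dtype=np.int64)

    max_cover = grid.window // grid.step + 1
    for chrom, grp in points.groupby("chrom", sort=False):
        if chrom not in grid.chrom_lengths:
            raise KeyError(f"chromosome {chrom!r} not in window grid")
        nw = grid.n_windows(chrom)
        pos = grp["pos"].to_numpy()
        beyond = pos >= grid.chrom_lengths[chrom]
        if beyond.any():
            logger.warning(
                "%d points beyond %s length; counted in last window",
                int(beyond.sum()), chrom,
            )
        col = grp["sample"].map(sample_index).to_numpy() if samples else np.zeros(0)
        first = np.maximum(0, (pos - grid.window) // grid.step + 1)
        last = np.minimum(nw - 1, pos // grid.step)
        first = np.minimum(first, nw - 1)
        for j in range(max_cover):
            idx = first + j
            sel = idx <= last
            if not sel.any():
                break
            np.add.at(counts, (offsets[chrom] + idx[sel], col[sel]), 1)
    return windows, counts


# ---------------------------------------------------------------------------
# Negative-binomial window test


def estimate_dispersions(
    counts: np.ndarray, group_a: np.ndarray, group_b: np.ndarray, n_bins: int = 20
) -> np.ndarray:
    """Binned method-of-moments NB dispersion, shared across similar-mean windows.

    The raw per-window estimate (pooled within-group variance v, overall mean
    m) is alpha = (v - m) / m^2; windows are pooled into ``n_bins`` quantile
    bins of the mean and each window receives its bin's average, floored at
    1e-4.  Pooling stabilises the estimate at 2-3 replicates per group.
    """
    m = counts.mean(axis=1)
    n_a, n_b = int(group_a.sum()), int(group_b.sum())
    dof = n_a + n_b - 2
    if dof <= 0:
        return np.full(counts.shape[0], DISPERSION_FLOOR)
    ma = counts[:, group_a].mean(axis=1, keepdims=True)
    mb = counts[:, group_b].mean(axis=1, keepdims=True)
    ss = ((counts[:, group_a] - ma) ** 2).sum(axis=1)
    ss += ((counts[:, group_b] - mb) ** 2).sum(axis=1)
    v = ss / dof
    alpha = np.full(counts.shape[0], DISPERSION_FLOOR)
    pos = m > 0
    if not pos.any():
        return alpha
    raw = (v[pos] - m[pos]) / m[pos] ** 2
    mpos = m[pos]
    edges = np.unique(np.quantile(mpos, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # all positive means identical: one pooled bin
        alpha[pos] = max(float(raw.mean()), DISPERSION_FLOOR)
        return alpha
    bins = np.clip(np.searchsorted(edges, mpos, side="right") - 1, 0, len(edges) - 2)
    alpha_pos = np.full(mpos.size, DISPERSION_FLOOR)
    for b in range(len(edges) - 1):
        sel = bins == b
        if sel.any():
            alpha_pos[sel] = max(float(raw[sel].mean()), DISPERSION_FLOOR)
    alpha[pos] = alpha_pos
    return alpha


def _nb_loglik(x: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of NB log-pmf with mean mu and dispersion alpha (var = mu + alpha mu^2)."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), x.shape)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float)[:, None], x.shape)
    r = 1.0 / alpha
    ll = np.where(
        mu > 0,
        stats.nbinom.logpmf(x, r, r / (r + np.maximum(mu, 1e-300))),
        np.where(x == 0, 0.0, -np.inf),
    )
    return ll.sum(axis=1)


def nb_test(
    counts: np.ndarray,
    groups: Sequence[str],
    pseudocount: float = 1.0,
    dispersion: np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test per window.

    ``counts`` is (windows x samples); ``groups`` assigns each column to one
    of exactly two group labels (first label encountered = group 1, reference).
    log2FC is log2((m2 + c)/(m1 + c)) with pseudocount c.  The test compares
    a shared mean against per-group means with a common (estimated)
    dispersion; the statistic is referred to chi-square with 1 df.
    All-zero windows return p = 1 and log2FC = 0.
    """
    counts = np.asarray(counts)
    groups = list(groups)
    if counts.shape[1] != len(groups):
        raise ValueError("one group label per counts column required")
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    ga = np.array([g == labels[0] for g in groups])
    gb = ~ga
    if dispersion is None:
        dispersion = estimate_dispersions(counts, ga, gb)

    m1 = counts[:, ga].mean(axis=1)
    m2 = counts[:, gb].mean(axis=1)
    m0 = counts.mean(axis=1)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))

    ll0 = _nb_loglik(counts, m0[:, None], dispersion)
    ll1 = _nb_loglik(counts[:, ga], m1[:, None], dispersion) + _nb_loglik(
        counts[:, gb], m2[:, None], dispersion
    )
    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    pvalue = stats.chi2.sf(lrt, df=1)

    allzero = m0 == 0
    pvalue[allzero] = 1.0
    log2fc[allzero] = 0.0
    return pd.DataFrame(
        {
            "mean_a": m1,
            "mean_b": m2,
            "log2fc": log2fc,
            "dispersion": dispersion,
            "pvalue": pvalue,
            "total_count": counts.sum(axis=1),
        }
    )


def adjust_pvalues(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def merge_windows(
    windows: pd.DataFrame,
    results: pd.DataFrame,
    threshold: float = 0.05,
    call_on: str = "padj",
) -> list[DifferentialRegion]:
    """Merge significant same-direction windows into differential regions.

    Window-level BH adjustment is computed (if absent) before merging.
    Windows with ``call_on`` (padj or pvalue) < threshold are significant;
    overlapping or book-ended significant windows of the same direction fuse
    into one region carrying the minimum p, minimum window padj, and the
    count-weighted mean log2FC of its windows.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    res = results.copy()
    if "padj" not in res.columns:
        res["padj"] = adjust_pvalues(res["pvalue"].to_numpy())
    df = pd.concat([windows.reset_index(drop=True), res.reset_index(drop=True)], axis=1)
    sig = df[df[call_on] < threshold].copy()
    if sig.empty:
        return []
    sig["direction"] = np.where(sig["log2fc"] > 0, "up", "down")
    sig = sig.sort_values(["chrom", "start", "end"], kind="mergesort")

    regions: list[DifferentialRegion] = []
    open_rows: dict[str, list] = {}  # direction -> accumulated window rows

    def flush(direction: str) -> None:
        rows = open_rows.pop(direction, None)
        if not rows:
            return
        block = pd.DataFrame(rows)
        weights = block["total_count"].to_numpy(dtype=float)
        if weights.sum() == 0:
            weights = np.ones(len(block))
        regions.append(
            DifferentialRegion(
                chrom=block["chrom"].iloc[0],
                start=int(block["start"].min()),
                end=int(block["end"].max()),
                log2fc=float(np.average(block["log2fc"], weights=weights)),
                pvalue=float(block["pvalue"].min()),
                padj=float(block["padj"].min()),
                direction=direction,
            )
        )

    prev_chrom = None
    ends: dict[str, int] = {}
    for row in sig.itertuples():
        d = row.direction
        if row.chrom != prev_chrom:
            for dd in list(open_rows):
                flush(dd)
            ends = {}
            prev_chrom = row.chrom
        if d in open_rows and row.start <= ends[d]:
            open_rows[d].append(row._asdict())
            ends[d] = max(ends[d], row.end)
        else:
            flush(d)
            open_rows[d] = [row._asdict()]
            ends[d] = row.end
    for dd in list(open_rows):
        flush(dd)
    regions.sort(key=lambda r: (r.chrom, r.start, r.end, r.direction))
    return regions


def filter_differential(
    regions: Sequence[DifferentialRegion],
    padj_max: float = 0.05,
    min_log2fc: float = 0.0,
) -> list[DifferentialRegion]:
    """Keep regions with padj < padj_max and log2FC > min_log2fc (both strict)."""
    return [r for r in regions if r.padj < padj_max and r.log2fc > min_log2fc]


# ---------------------------------------------------------------------------
# Coverage tracks and TSS profiles


def coverage_track(
    frags: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    adjusted_sf: float = 1.0,
    bin_size: int = 1,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-bin fragment coverage for one sample's (target-genome) fragments.

    Scaling is applied by seeded Bernoulli downsampling with ``adjusted_sf``
    before counting — track values themselves are never multiplied by the
    factor, so scaling cannot be applied twice.  With bin_size 1 the value is
    the number of fragments covering each base; for larger bins, per-base
    coverage is summed within the bin, so the track total always equals the
    summed length of the kept fragments.
    """
    from .spikein import downsample_fragments

    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    if adjusted_sf < 1.0:
        frags = downsample_fragments(frags, adjusted_sf, seed)
    track: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        cov = np.zeros(length + 1, dtype=np.int64)
        sub = frags[frags["chrom"] == chrom]
        if len(sub):
            starts = np.clip(sub["start"].to_numpy(), 0, length)
            ends = np.clip(sub["end"].to_numpy(), 0, length)
            np.add.at(cov, starts, 1)
            np.add.at(cov, ends, -1)
        cov = np.cumsum(cov[:-1])
        if bin_size > 1:
            n_bins = -(-length // bin_size)
            padded = np.zeros(n_bins * bin_size, dtype=np.int64)
            padded[:length] = cov
            cov = padded.reshape(n_bins, bin_size).sum(axis=1)
        track[chrom] = cov
    return track


def tss_profile(
    track: Mapping[str, np.ndarray],
    tss: TSSAnnotation,
    flank: int = 2000,
    bin_size: int = 10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Strand-aware mean signal in bins around each TSS.

    Rows are TSSs, columns the ``2*flank/bin_size`` bins from -flank to
    +flank in transcription orientation (minus-strand rows are reversed).
    TSSs whose flank would run off the chromosome get an all-NaN row and are
    excluded from the mean profile (second return value: column means).
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    rows = []
    ids = []
    for rec in tss:
        ids.append(rec.gene_id)
        arr = track.get(rec.chrom)
        lo, hi = rec.tss - flank, rec.tss + flank
        if arr is None or lo < 0 or hi > arr.size:
            rows.append(np.full(n_bins, np.nan))
            continue
        window = np.asarray(arr[lo:hi], dtype=float)
        binned = window.reshape(n_bins, bin_size).mean(axis=1)
        if rec.strand == "-":
            binned = binned[::-1]
        rows.append(binned)
    matrix = pd.DataFrame(rows, index=ids)
    complete = matrix.dropna()
    mean_profile = (
        complete.to_numpy().mean(axis=0) if len(complete) else np.full(n_bins, np.nan)
    )
    return matrix, mean_profile
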