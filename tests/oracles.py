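"""Independent brute-force oracles and random-instance builders for tests."""

import numpy as np

from chiprx.core_io import GenomicInterval, IntervalSet


def random_interval_set(rng, chrom_len=10_000, max_n=20, chroms=("chrA", "chrB")):
    """A random (possibly overlapping, unsorted) interval set on toy chromosomes."""
    n = int(rng.integers(0, max_n + 1))
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, chrom_len - 1))
        length = int(rng.integers(1, 500))
        ivs.append(GenomicInterval(chrom, start, min(start + length, chrom_len)))
    return IntervalSet(ivs)


def base_mask(iset, chrom, chrom_len=10_000):
    """Per-base boolean coverage mask — the brute-force oracle for set algebra."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in iset:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def coverage_counts(isets, chrom, chrom_len=10_000):
    """Per-base replicate-coverage counts (each set merged first)."""
    cov = np.zeros(chrom_len, dtype=int)
    for s in isets:
        cov += base_mask(s.merge(), chrom, chrom_len).astype(int)
    return cov


def mask_to_spans(mask):
    """Maximal True runs of a boolean mask as (start, end) pairs."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def spans_of(iset, chrom):
    return [(iv.start, iv.end) for iv in iset if iv.chrom == chrom]
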