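"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator is a pure function of (seed, parameters): rerunning with the
same arguments is bit-identical.  Defaults emulate the study conditions the
pipeline is designed for — a two-genome ChIP-Rx read population with a 20%
spike-in proportion, replicate groups of three genotypes with planted
differential regions under negative-binomial count noise, enhancer interval
sets, and sequences with planted motif occurrences.  Truth records carry
everything needed to score recall, false-discovery rate and parameter
recovery downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, IntervalSet
from .motifs import MotifMatrix
from .spikein import SpikeInCounts
from .windows_diff import WindowGrid

SPIKE_FRACTION_DEFAULT = 0.20  # exogenous chromatin proportion of the mix
FRAGMENT_LENGTH_DEFAULT = 300


@dataclass
class SimulationTruth:
    """Ground-truth record serialised alongside generated data."""

    seed: int
    params: dict = field(default_factory=dict)
    occupancy: dict[str, float] = field(default_factory=dict)
    differential_regions: list[dict] = field(default_factory=list)
    motif_positions: dict[str, list[int]] = field(default_factory=dict)
    enhancers: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def simulate_genome(
    seed: int, n_chrom: int = 1, chrom_len: int = 100_000, gc: float = 0.5
) -> dict[str, str]:
    """I.i.d. random genome at the stated GC content."""
    if not (0 < gc < 1):
        raise ValueError("gc must lie strictly inside (0, 1)")
    if chrom_len < 1000:
        raise ValueError("chrom_len must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(bases[rng.choice(4, size=chrom_len, p=p)])
        for i in range(n_chrom)
    }


def simulate_spikein_experiment(
    seed: int,
    occupancy: Mapping[str, float],
    depth: int = 100_000,
    spike_fraction: float = SPIKE_FRACTION_DEFAULT,
    chrom: str = "chr1",
    chrom_len: int = 1_000_000,
    fragment_length: int = FRAGMENT_LENGTH_DEFAULT,
) -> tuple[dict[str, SpikeInCounts], pd.DataFrame, SimulationTruth]:
    """Two-genome read populations with sample-specific global occupancy.

    Target-genome IP read counts are Poisson with mean ``depth * occupancy``;
    spike-in IP counts Poisson with mean ``depth * spike_fraction`` — the
    exogenous material is a fixed proportion of every sample, which is what
    makes it a usable normaliser.  Input counts are occupancy-independent
    (target mean ``depth``, spike-in mean ``depth * spike_fraction``).
    """
    if any(r <= 0 for r in occupancy.values()):
        raise ValueError("occupancy ratios must be positive")
    rng = np.random.default_rng(seed)
    counts: dict[str, SpikeInCounts] = {}
    frames = []
    for sample in occupancy:
        occ = occupancy[sample]
        if depth == 0:
            counts[sample] = SpikeInCounts(0, 0, 0, 0)
            continue
        h_ip = int(rng.poisson(depth * occ))
        d_ip = int(rng.poisson(depth * spike_fraction))
        h_in = int(rng.poisson(depth))
        d_in = int(rng.poisson(depth * spike_fraction))
        counts[sample] = SpikeInCounts(h_ip, d_ip, h_in, d_in)
        for genome, role, n in (
            ("target", "IP", h_ip),
            ("spikein", "IP", d_ip),
            ("target", "input", h_in),
            ("spikein", "input", d_in),
        ):
            starts = rng.integers(0, chrom_len - fragment_length, size=n)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + fragment_length,
                        "genome": genome,
                        "sample": sample,
                        "role": role,
                    }
                )
            )
    frags = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end", "genome", "sample", "role"])
    )
    truth = SimulationTruth(
        seed=seed,
        params={
            "depth": depth,
            "spike_fraction": spike_fraction,
            "fragment_length": fragment_length,
        },
        occupancy=dict(occupancy),
    )
    return counts, frags, truth


def simulate_differential_tags(
    seed: int,
    grid: WindowGrid,
    groups: Mapping[str, Sequence[str]],
    base_mean: float = 50.0,
    dispersion: float = 0.1,
    planted: Sequence[tuple[GenomicInterval, float]] = (),
    emit_fragments: bool = True,
    fragment_length: int = FRAGMENT_LENGTH_DEFAULT,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame | None, SimulationTruth]:
    """Per-window NB counts for two replicate groups with planted fold changes.

    Counts are NB(mean, dispersion) per window and replicate; inside each
    planted region the mean of the *second* group is multiplied by the fold.
    When ``emit_fragments`` is true, each count is also materialised as that
    many fixed-length fragments with midpoints uniform in the window, so the
    fragment-extension and window-counting stages can be exercised
    end-to-end.  Returns (window frame, counts, fragments or None, truth).
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    for iv, fold in planted:
        if fold <= 0:
            raise ValueError("planted folds must be positive")
    spans = sorted(
        ((iv.chrom, iv.start, iv.end) for iv, _ in planted)
    )
    for a, b in zip(spans, spans[1:]):
        if a[0] == b[0] and b[1] < a[2]:
            raise ValueError("planted regions must not overlap")

    rng = np.random.default_rng(seed)
    windows = grid.window_frame()
    (name_a, reps_a), (name_b, reps_b) = groups.items()
    samples = list(reps_a) + list(reps_b)
    group_of = {s: name_a for s in reps_a} | {s: name_b for s in reps_b}

    fold_per_window = np.ones(len(windows))
    for iv, fold in planted:
        hit = (
            (windows["chrom"] == iv.chrom)
            & (windows["start"] < iv.end)
            & (windows["end"] > iv.start)
        ).to_numpy()
        fold_per_window[hit] = fold

    r = 1.0 / dispersion
    counts = np.empty((len(windows), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = np.where(group_of[s] == name_b, base_mean * fold_per_window, base_mean)
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    frags: pd.DataFrame | None = None
    if emit_fragments:
        half = fragment_length // 2
        frames = []
        starts_arr = windows["start"].to_numpy()
        chrom_arr = windows["chrom"].to_numpy()
        for j, s in enumerate(samples):
            reps = np.repeat(np.arange(len(windows)), counts[:, j])
            mids = starts_arr[reps] + rng.integers(
                0, grid.window, size=reps.size
            )
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom_arr[reps],
                        "start": np.maximum(mids - half, 0),
                        "end": np.maximum(mids - half, 0) + fragment_length,
                        "genome": "target",
                        "sample": s,
                        "role": "IP",
                    }
                )
            )
        frags = pd.concat(frames, ignore_index=True)

    truth = SimulationTruth(
        seed=seed,
        params={
            "base_mean": base_mean,
            "dispersion": dispersion,
            "window": grid.window,
            "step": grid.step,
            "groups": {k: list(v) for k, v in groups.items()},
        },
        differential_regions=[
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "fold": fold}
            for iv, fold in planted
        ],
    )
    return windows, counts, frags, truth


def simulate_enhancers(
    seed: int,
    chrom_lengths: Mapping[str, int],
    n: int = 100,
    width_range: tuple[int, int] = (200, 1000),
    max_tries: int = 1000,
) -> IntervalSet:
    """Non-overlapping enhancer-like intervals with uniform widths.

    Widths are drawn uniformly from ``width_range`` (inclusive); placement
    retries up to ``max_tries`` times per interval before giving up.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    placed: list[GenomicInterval] = []
    for _ in range(n):
        for attempt in range(max_tries):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            width = int(rng.integers(width_range[0], width_range[1] + 1))
            limit = chrom_lengths[chrom] - width
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            cand = GenomicInterval(chrom, start, start + width)
            if not any(cand.overlaps(p) for p in placed if p.chrom == chrom):
                placed.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place {n} non-overlapping intervals in {max_tries} tries"
            )
    return IntervalSet(placed, label="enhancers").sort()


def plant_motifs(
    seed: int,
    sequences: Mapping[str, str],
    motif: MotifMatrix,
    fraction: float = 0.3,
    offset: int | None = None,
) -> tuple[dict[str, str], SimulationTruth]:
    """Write the motif consensus into a seeded subset of sequences.

    A ``fraction`` of the sequences (chosen without replacement) receive one
    consensus instance at ``offset`` (or a uniform random valid offset when
    None); planted positions are recorded in the truth.  Sequences shorter
    than the motif are never selected.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    consensus = motif.consensus()
    k = len(consensus)
    ids = list(sequences)
    eligible = [i for i in ids if len(sequences[i]) >= k]
    n_plant = int(round(fraction * len(ids)))
    n_plant = min(n_plant, len(eligible))
    chosen = set(
        rng.choice(len(eligible), size=n_plant, replace=False).tolist()
    ) if n_plant else set()
    out: dict[str, str] = {}
    truth = SimulationTruth(
        seed=seed, params={"motif": motif.name, "fraction": fraction}
    )
    eligible_index = {sid: j for j, sid in enumerate(eligible)}
    for sid in ids:
        seq = sequences[sid]
        j = eligible_index.get(sid)
        if j is not None and j in chosen:
            pos = (
                offset
                if offset is not None
                else int(rng.integers(0, len(seq) - k + 1))
            )
            seq = seq[:pos] + consensus + seq[pos + k :]
            truth.motif_positions[sid] = [pos]
        out[sid] = seq
    return out, truth
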