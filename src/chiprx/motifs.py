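"""PWM scanning with exact score p-values and known-motif enrichment.

A position probability matrix is converted to integer-discretised log-odds
scores against a background model; the exact null distribution of the score
of a random background k-mer is then obtained by dynamic programming
(convolution of per-position score distributions), giving an exact tail
p-value for any threshold on the discretisation grid.  Enrichment between a
target and a background peak set uses ZOOPS counting (zero or one occurrence
per sequence) and a one-sided hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import GenomicInterval, IntervalSet

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

DEFAULT_GRID_STEPS = 1000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifMatrix:
    """A named position probability matrix over A, C, G, T."""

    name: str
    probs: np.ndarray  # (k, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(
            self, "background", np.asarray(self.background, dtype=float)
        )
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probability matrix must be (k, 4)")
        if (probs < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix columns must each sum to 1")
        if (self.background <= 0).any():
            raise ValueError("background frequencies must be positive")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based, on the forward sequence
    strand: str
    score: float
    pvalue: float


@dataclass(frozen=True)
class ScoredMotif:
    """Integer-discretised log-odds matrix with its exact null tail."""

    motif: MotifMatrix
    int_scores: np.ndarray  # (k, 4) integers
    granularity: float
    tail: np.ndarray  # tail[s - smin] = P(score >= s) under background
    smin: int

    @property
    def width(self) -> int:
        return self.int_scores.shape[0]

    def pvalue(self, int_score: int) -> float:
        idx = int_score - self.smin
        if idx <= 0:
            return 1.0
        if idx >= self.tail.size:
            return float(self.tail[-1])
        return float(self.tail[idx])


def log_odds(
    motif: MotifMatrix,
    pseudocount: float = 1e-4,
    grid_steps: int = DEFAULT_GRID_STEPS,
) -> tuple[np.ndarray, float]:
    """Integer-discretised log2-odds scores against the background.

    Raw scores are log2((p + pseudocount) / bg); they are rounded onto a grid
    of granularity g = (total score range) / grid_steps shared by all
    positions, so any k-mer score changes by less than g*k.
    """
    raw = np.log2((motif.probs + pseudocount) / motif.background)
    span = float((raw.max(axis=1) - raw.min(axis=1)).sum())
    g = span / grid_steps if span > 0 else 1.0
    return np.rint(raw / g).astype(np.int64), g


def score_distribution(
    int_scores: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, int]:
    """Exact pmf of the total integer score of a random background k-mer.

    Convolves the per-position score distributions by dynamic programming;
    returns (pmf, smin) where pmf[s - smin] = P(score == s).
    """
    smin = int(int_scores.min(axis=1).sum())
    smax = int(int_scores.max(axis=1).sum())
    pmf = np.zeros(smax - smin + 1)
    pmf[0] = 1.0  # index 0 tracks the sum of per-position minima so far
    for pos in range(int_scores.shape[0]):
        row = int_scores[pos]
        rmin = int(row.min())
        new = np.zeros_like(pmf)
        for b in range(4):
            shift = int(row[b]) - rmin
            if shift == 0:
                new += background[b] * pmf
            else:
                new[shift:] += background[b] * pmf[:-shift]
        pmf = new
    return pmf, smin


def score_pvalue(scored: ScoredMotif, threshold: int) -> float:
    """Exact P(score >= threshold) for a random background k-mer."""
    return scored.pvalue(int(threshold))


def prepare_motif(
    motif: MotifMatrix,
    pseudocount: float = 1e-4,
    grid_steps: int = DEFAULT_GRID_STEPS,
) -> ScoredMotif:
    """Discretise a motif and precompute its exact null tail distribution."""
    int_scores, g = log_odds(motif, pseudocount, grid_steps)
    pmf, smin = score_distribution(int_scores, motif.background)
    tail = np.cumsum(pmf[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoredMotif(motif, int_scores, g, tail, smin)


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base indices; anything outside ACGT becomes -1."""
    idx = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return idx


def _window_scores(idx: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total integer score for every k-window; second array flags valid (N-free) windows."""
    k = int_scores.shape[0]
    n = idx.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    safe = np.where(idx < 0, 0, idx)
    for pos in range(k):
        scores += int_scores[pos][safe[pos : pos + n]]
        valid &= idx[pos : pos + n] >= 0
    return scores, valid


def scan_sequences(
    sequences: Mapping[str, str],
    motif: MotifMatrix | ScoredMotif,
    p_max: float = 1e-4,
) -> list[MotifHit]:
    """Scan both strands for motif occurrences with exact p-value <= p_max.

    Windows containing non-ACGT characters are skipped.  Hits are reported
    with the 0-based offset of the window on the forward sequence; a hit on
    the minus strand means the reverse complement of that window matches.
    Hits are sorted by (sequence id, offset, strand).
    """
    scored = motif if isinstance(motif, ScoredMotif) else prepare_motif(motif)
    k = scored.width
    hits: list[MotifHit] = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < k:
            continue
        fwd = _encode(seq)
        rev = _encode(reverse_complement(seq))
        for strand, idx in (("+", fwd), ("-", rev)):
            scores, valid = _window_scores(idx, scored.int_scores)
            for pos in np.flatnonzero(valid):
                p = scored.pvalue(int(scores[pos]))
                if p <= p_max:
                    offset = int(pos) if strand == "+" else len(seq) - k - int(pos)
                    hits.append(
                        MotifHit(
                            seq_id,
                            offset,
                            strand,
                            float(scores[pos] * scored.granularity),
                            p,
                        )
                    )
    hits.sort(key=lambda h: (h.seq_id, h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Enrichment


def resize_regions(regions: IntervalSet, width: int = 300) -> IntervalSet:
    """Fix every region to ``width`` bp centred on its midpoint (floored at 0)."""
    out = []
    for iv in regions:
        mid = iv.midpoint
        start = max(0, mid - width // 2)
        out.append(GenomicInterval(iv.chrom, start, start + width, iv.strand, iv.name))
    return IntervalSet(out, label=regions.label)


def extract_sequences(
    regions: IntervalSet, genome: Mapping[str, str]
) -> dict[str, str]:
    """Pull the genomic sequence of each region, clipped to chromosome ends."""
    out: dict[str, str] = {}
    for i, iv in enumerate(regions):
        chrom_seq = genome[iv.chrom]
        out[f"{iv.chrom}:{iv.start}-{iv.end}|{i}"] = chrom_seq[
            iv.start : min(iv.end, len(chrom_seq))
        ].upper()
    return out


def zoops_hit_count(
    sequences: Mapping[str, str], scored: ScoredMotif, p_max: float
) -> int:
    """Number of sequences with at least one occurrence (ZOOPS counting)."""
    hits = scan_sequences(sequences, scored, p_max)
    return len({h.seq_id for h in hits})


def motif_enrichment(
    target: IntervalSet,
    background: IntervalSet,
    genome: Mapping[str, str],
    motifs: Sequence[MotifMatrix],
    p_max: float = 1e-4,
    width: int = 300,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each motif in target vs background.

    Both interval sets are resized to ``width`` bp around their midpoints and
    their sequences extracted; per motif, sequences with >= 1 hit at
    ``p_max`` are counted (ZOOPS) and the one-sided hypergeometric tail
    P(X >= observed) over the pooled sequence collection is reported.
    """
    if not len(target) or not len(background):
        raise ValueError("target and background must both be non-empty")
    t_seqs = extract_sequences(resize_regions(target, width), genome)
    b_seqs = extract_sequences(resize_regions(background, width), genome)
    n_t, n_b = len(t_seqs), len(b_seqs)
    rows = []
    for motif in motifs:
        scored = prepare_motif(motif)
        k_t = zoops_hit_count(t_seqs, scored, p_max)
        k_b = zoops_hit_count(b_seqs, scored, p_max)
        p = hypergeometric_enrichment(k_t, n_t, k_b, n_b)
        rows.append(
            {
                "motif": motif.name,
                "target_hits": k_t,
                "target_n": n_t,
                "background_hits": k_b,
                "background_n": n_b,
                "pvalue": p,
            }
        )
    df = pd.DataFrame(rows).sort_values(["pvalue", "motif"], kind="mergesort")
    return df.reset_index(drop=True)


def hypergeometric_enrichment(k_t: int, n_t: int, k_b: int, n_b: int) -> float:
    """One-sided tail P(X >= k_t) drawing n_t from a pool with k_t+k_b successes."""
    population = n_t + n_b
    successes = k_t + k_b
    return float(hypergeom.sf(k_t - 1, population, successes, n_t))


def assemble_heatmap(
    enrichment_tables: Mapping[str, pd.DataFrame], top_n: int = 20
) -> pd.DataFrame:
    """Union-of-top-N enrichment p-value matrix across peak lists.

    Rows are the union of each list's ``top_n`` most enriched motifs
    (ascending p, ties broken by motif name); each cell is that list's p for
    the motif, and 1.0 where the motif was not found in that list's table.
    Rows are ordered by best p across lists, then name.
    """
    if not enrichment_tables:
        raise ValueError("at least one enrichment table required")
    union: dict[str, None] = {}
    for table in enrichment_tables.values():
        top = table.sort_values(["pvalue", "motif"], kind="mergesort").head(top_n)
        for name in top["motif"]:
            union.setdefault(name, None)
    motifs_union = list(union)
    data = {}
    for list_name, table in enrichment_tables.items():
        lookup = dict(zip(table["motif"], table["pvalue"]))
        data[list_name] = [float(lookup.get(m, 1.0)) for m in motifs_union]
    heatmap = pd.DataFrame(data, index=motifs_union)
    order = sorted(motifs_union, key=lambda m: (heatmap.loc[m].min(), m))
    return heatmap.loc[order]


# ---------------------------------------------------------------------------
# MEME minimal format I/O


def read_meme(path: str | Path) -> list[MotifMatrix]:
    """Read motifs from MEME minimal text format."""
    motifs: list[MotifMatrix] = []
    background = np.full(4, 0.25)
    name = None
    rows: list[list[float]] = []
    expect_bg = False

    def flush() -> None:
        nonlocal name, rows
        if name is not None and rows:
            motifs.append(MotifMatrix(name, np.array(rows), background.copy()))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if expect_bg:
                parts = line.split()
                freqs = {parts[i]: float(parts[i + 1]) for i in range(0, len(parts), 2)}
                background = np.array([freqs.get(b, 0.25) for b in ALPHABET])
                expect_bg = False
            elif line.startswith("Background letter frequencies"):
                expect_bg = True
            elif line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                continue
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                rows.append([float(x) for x in line.split()])
    flush()
    return motifs


def write_meme(motifs: Sequence[MotifMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
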