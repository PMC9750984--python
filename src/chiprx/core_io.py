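"""Interval data model and readers/writers for the standard text formats.

Coordinates are 0-based, half-open throughout (BED convention): an interval
``[start, end)`` covers ``end - start`` bases.  Readers for 1-based dialects
must convert at this boundary.  Chromosome names are compared by exact string
equality; use :func:`rename_chroms` to reconcile mismatched annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("chiprx")

VALID_STRANDS = {"+", "-", "."}
VALID_GENOMES = {"target", "spikein"}
VALID_ROLES = {"IP", "input"}

FRAGMENT_COLUMNS = ["chrom", "start", "end", "genome", "sample", "role"]


class BedParseError(ValueError):
    """Raised for malformed BED input, naming the offending line."""


class IntervalValidationError(ValueError):
    """Raised when interval coordinates violate 0 <= start < end."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntervalValidationError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise IntervalValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    The set records whether it is sorted by (chrom, start) and whether its
    members are merged (pairwise non-overlapping, non-abutting).  All peak
    algebra requires merged operands; call :meth:`merge` first.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(label={self.label!r}, n={len(self)})"

    @property
    def is_sorted(self) -> bool:
        key = [(iv.chrom, iv.start, iv.end) for iv in self.intervals]
        return key == sorted(key)

    @property
    def is_merged(self) -> bool:
        if not self.is_sorted:
            return False
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                return False
        return True

    def sort(self) -> "IntervalSet":
        out = IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
            label=self.label,
        )
        return out

    def merge(self) -> "IntervalSet":
        """Union of all members: overlapping or book-ended spans are fused."""
        merged: list[GenomicInterval] = []
        for iv in self.sort():
            if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
                if iv.end > merged[-1].end:
                    merged[-1] = replace(merged[-1], end=iv.end)
            else:
                merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return IntervalSet(merged, label=self.label)

    def total_bases(self) -> int:
        return sum(iv.length for iv in self.merge())

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """(n, 2) start/end arrays per chromosome, sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {
            c: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
            for c, pairs in out.items()
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name or "." for iv in self.intervals],
                "score": [0.0 if iv.score is None else iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str


class TSSAnnotation:
    """Transcription start sites, one per gene id (unique ids enforced)."""

    def __init__(self, records: Iterable[TSSRecord]):
        self.records = list(records)
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in TSS annotation")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TSSRecord]:
        return iter(self.records)

    def by_chrom(self) -> dict[str, list[TSSRecord]]:
        out: dict[str, list[TSSRecord]] = {}
        for r in self.records:
            out.setdefault(r.chrom, []).append(r)
        for recs in out.values():
            recs.sort(key=lambda r: (r.tss, r.gene_id))
        return out


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet`.

    Extra columns beyond the six standard ones are ignored.  Malformed lines
    raise :class:`BedParseError` naming the line number; zero-length or
    inverted intervals raise :class:`IntervalValidationError`.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, score)
                )
            except IntervalValidationError as exc:
                raise IntervalValidationError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, label=label if label is not None else path.stem)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED; emits 6 columns when any member has strand/name/score, else 3."""
    six = any(
        iv.strand != "." or iv.name is not None or iv.score is not None
        for iv in iset
    )
    with open(path, "w") as fh:
        for iv in iset:
            if six:
                score = 0.0 if iv.score is None else iv.score
                score_str = str(int(score)) if float(score).is_integer() else f"{score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score_str}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Fragment tables

def validate_fragments(frags: pd.DataFrame) -> pd.DataFrame:
    """Validate a fragment table (chrom, start, end, genome, sample, role)."""
    missing = [c for c in FRAGMENT_COLUMNS if c not in frags.columns]
    if missing:
        raise ValueError(f"fragment table missing columns: {missing}")
    if len(frags):
        bad_genome = set(frags["genome"].unique()) - VALID_GENOMES
        if bad_genome:
            raise ValueError(f"unknown genome labels: {sorted(bad_genome)}")
        bad_role = set(frags["role"].unique()) - VALID_ROLES
        if bad_role:
            raise ValueError(f"unknown role labels: {sorted(bad_role)}")
        if (frags["end"] <= frags["start"]).any():
            raise ValueError("fragment with end <= start")
    return frags


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a TSV fragment table; surrogate for filtered, scaled alignments."""
    frags = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "genome": str, "sample": str, "role": str},
    )
    if "strand" not in frags.columns:
        frags["strand"] = "."
    return validate_fragments(frags)


def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    validate_fragments(frags)
    frags.to_csv(path, sep="\t", index=False)


def fragment_tallies(frags: pd.DataFrame) -> pd.DataFrame:
    """Read counts per (sample, genome, role); empty input gives empty tallies."""
    if not len(frags):
        return pd.DataFrame(columns=["sample", "genome", "role", "count"])
    out = (
        frags.groupby(["sample", "genome", "role"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# TSS tables, bedGraph, FASTA, config


def read_tss(path: str | Path) -> TSSAnnotation:
    """Read a TSV of (gene_id, chrom, tss, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    return TSSAnnotation(
        TSSRecord(r.gene_id, r.chrom, int(r.tss), r.strand) for r in df.itertuples()
    )


def write_tss(tss: TSSAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in tss],
            "chrom": [r.chrom for r in tss],
            "tss": [r.tss for r in tss],
            "strand": [r.strand for r in tss],
        }
    ).to_csv(path, sep="\t", index=False)


def write_bedgraph(track: Mapping[str, np.ndarray], path: str | Path, bin_size: int = 1) -> None:
    """Write a per-bin track as bedGraph, run-length compressing equal bins."""
    with open(path, "w") as fh:
        for chrom in track:
            values = np.asarray(track[chrom], dtype=float)
            if values.size == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v == 0:
                    continue
                v_str = str(int(v)) if float(v).is_integer() else f"{v:g}"
                fh.write(f"{chrom}\t{s * bin_size}\t{e * bin_size}\t{v_str}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered dict of upper-cased sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_config(path: str | Path | None, overrides: Mapping | None = None) -> dict:
    """Load a YAML config; keys in ``overrides`` (not None) win."""
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        if value is not None:
            cfg[key] = value
    return cfg


def rename_chroms(iset: IntervalSet, mapping: Mapping[str, str]) -> IntervalSet:
    """Apply a chromosome rename map (for annotations with other naming)."""
    return IntervalSet(
        [replace(iv, chrom=mapping.get(iv.chrom, iv.chrom)) for iv in iset],
        label=iset.label,
    )


def intervals_from_arrays(
    chrom: str, spans: Sequence[tuple[int, int]] | np.ndarray, **kw
) -> list[GenomicInterval]:
    return [GenomicInterval(chrom, int(s), int(e), **kw) for s, e in spans]
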