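"""Genomic intervals, peak/gene I/O, peak intersection and gene assignment.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Peaks are reduced to a single anchor position (the
integer-floor midpoint by default, or an explicit summit) for gene
assignment and for the promoter/gene-body location categories.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Location",
    "PeakAssignment",
    "read_bed",
    "write_bed",
    "read_genes",
    "intersect_peaks",
    "assign_peak",
    "assign_peaks",
    "overlap_with_sites",
    "top_sites_by_signal",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` with optional score/name/strand."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)
    name: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def center(self) -> int:
        """Integer-floor midpoint of the interval."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware single-span gene model.

    The transcription start site (TSS) is the 5'-most transcribed base:
    ``start`` on the plus strand, ``end - 1`` on the minus strand.  The
    transcription termination site (TTS) is the opposite extremity.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


class Location(str, Enum):
    """Peak location category relative to its assigned gene.

    ``TSS``: anchor within +/- 1 kb of the annotated TSS.
    ``EXTENDED_PROMOTER``: anchor in the strand-aware [-10 kb, -1 kb) window
    upstream of the TSS.
    ``GENE_BODY``: anywhere else inside the assignment window.
    ``INTERGENIC``: no gene assigned.
    """

    TSS = "TSS"
    GENE_BODY = "GENE_BODY"
    EXTENDED_PROMOTER = "EXTENDED_PROMOTER"
    INTERGENIC = "INTERGENIC"


@dataclass(frozen=True)
class PeakAssignment:
    peak: GenomicInterval
    gene_id: str | None
    location: Location
    distance_to_tss: int | None

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.location is Location.INTERGENIC):
            raise ValueError("gene_id must be absent iff location is INTERGENIC")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED5/BED6 into intervals; malformed rows raise with their index."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: record {i}: fewer than 3 columns")
            try:
                iv = GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3] if len(fields) > 3 and fields[3] != "." else None,
                    score=float(fields[4]) if len(fields) > 4 and fields[4] != "." else None,
                    strand=fields[5] if len(fields) > 5 and fields[5] in "+-" else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: record {i}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a gene table: BED6 (gene_id in the name column) or 5-column
    tab-delimited (chrom, start, end, strand, gene_id), autodetected per row."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if len(f) >= 6:  # BED6
                    genes.append(GeneModel(f[0], int(f[1]), int(f[2]), f[5], f[3]))
                elif len(f) == 5:  # chrom start end strand gene_id
                    genes.append(GeneModel(f[0], int(f[1]), int(f[2]), f[3], f[4]))
                else:
                    raise ValueError("expected 5 or 6 columns")
            except ValueError as exc:
                raise ValueError(f"{path}: record {i}: {exc}") from exc
    return genes


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _build_tree(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def intersect_peaks(
    list_a: Sequence[GenomicInterval], list_b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """High-confidence co-bound peaks: every ``list_b`` interval overlapping
    (>= 1 shared base) at least one ``list_a`` interval, with the ``list_b``
    coordinates kept, deduplicated, ordered by (chrom, start, end)."""
    trees = _build_tree(list_a)
    hits: dict[tuple[str, int, int], GenomicInterval] = {}
    for iv in list_b:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            hits.setdefault((iv.chrom, iv.start, iv.end), iv)
    return sorted(hits.values(), key=lambda p: (p.chrom, p.start, p.end))


def _anchor(peak: GenomicInterval, center: str) -> int:
    if center == "midpoint":
        return peak.center
    if center == "summit":
        if peak.score is None:
            raise ValueError("summit anchoring requires a summit offset in score")
        return peak.start + int(peak.score)
    raise ValueError(f"unknown center mode {center!r}")


def assign_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    upstream_bp: int = 10_000,
    downstream_bp: int = 1_000,
    center: str = "midpoint",
    tss_halfwidth: int = 1_000,
) -> PeakAssignment:
    """Assign a peak to the gene whose strand-aware window
    ``[TSS - upstream_bp, TTS + downstream_bp]`` contains the peak anchor.

    With several candidate genes the one with the TSS nearest to the anchor
    wins; exact ties fall back to the lexicographically smallest gene_id.
    The location category is a partition of the window: ``TSS`` within
    +/- ``tss_halfwidth`` of the TSS, ``EXTENDED_PROMOTER`` for strand-aware
    signed distances in [-upstream_bp, -tss_halfwidth), ``GENE_BODY``
    otherwise.  Peaks hitting no window are ``INTERGENIC``.
    """
    if not genes:
        raise ValueError("gene table is empty")
    if upstream_bp <= 0 or downstream_bp <= 0:
        raise ValueError("assignment windows must be positive")
    pos = _anchor(peak, center)

    best: tuple[int, str, GeneModel] | None = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        if g.strand == "+":
            lo, hi = g.tss - upstream_bp, g.tts + downstream_bp
        else:
            lo, hi = g.tts - downstream_bp, g.tss + upstream_bp
        if not (lo <= pos <= hi):
            continue
        key = (abs(pos - g.tss), g.gene_id, g)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return PeakAssignment(peak, None, Location.INTERGENIC, None)

    gene = best[2]
    # signed distance in transcription direction: negative = upstream of TSS
    signed = pos - gene.tss if gene.strand == "+" else gene.tss - pos
    if abs(signed) <= tss_halfwidth:
        loc = Location.TSS
    elif -upstream_bp <= signed < -tss_halfwidth:
        loc = Location.EXTENDED_PROMOTER
    else:
        loc = Location.GENE_BODY
    return PeakAssignment(peak, gene.gene_id, loc, signed)


def assign_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    **kwargs,
) -> list[PeakAssignment]:
    return [assign_peak(p, genes, **kwargs) for p in peaks]


def assignments_to_frame(assignments: Sequence[PeakAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.peak.chrom for a in assignments],
            "start": [a.peak.start for a in assignments],
            "end": [a.peak.end for a in assignments],
            "peak_id": [a.peak.name for a in assignments],
            "gene_id": [a.gene_id for a in assignments],
            "location": [a.location.value for a in assignments],
            "distance_to_tss": [a.distance_to_tss for a in assignments],
        }
    )


def overlap_with_sites(
    peaks: Sequence[GenomicInterval], sites: Sequence[GenomicInterval]
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition peaks by >= 1 bp overlap with any site."""
    trees = _build_tree(sites)
    inside: list[GenomicInterval] = []
    outside: list[GenomicInterval] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is not None and tree.overlaps(p.start, p.end):
            inside.append(p)
        else:
            outside.append(p)
    return inside, outside


def top_sites_by_signal(
    sites: Sequence[GenomicInterval], n: int = 40_000
) -> list[GenomicInterval]:
    """The ``n`` highest-scoring sites; ties at the cutoff break by (chrom, start)."""
    for i, s in enumerate(sites):
        if s.score is None:
            raise ValueError(f"site {i} ({s.chrom}:{s.start}-{s.end}) has no score")
    if n >= len(sites):
        return list(sites)
    ranked = heapq.nsmallest(
        n, sites, key=lambda s: (-s.score, s.chrom, s.start, s.end)
    )
    return ranked
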