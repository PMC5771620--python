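"""Read-level signal extraction at peak-centered windows.

Reads (BED-like intervals with strand) are deduplicated, optionally
extended from their 5' end, piled up over windows centered on peak
midpoints, and scaled to reads/bp per 10^8 sequenced reads — the unit in
which all downstream signal matrices are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, read_bed

__all__ = [
    "ReadSet",
    "ASSAY_HALFWIDTHS",
    "LIBRARY_SCALE",
    "remove_duplicates",
    "extend_reads",
    "windowed_signal",
    "read_reads_bed",
    "read_reads_sam",
]

#: reads/bp values are scaled to this many sequenced reads
LIBRARY_SCALE = 100_000_000

#: default window halfwidths (bp) around the peak center, per assay type
ASSAY_HALFWIDTHS = {
    "tf": 250,           # transcription factors, CBP/p300, Pol II
    "histone": 1000,     # histone modifications (e.g. H3K27ac)
    "erna": 500,         # GRO-Seq enhancer RNA
    "nucleosome": 75,    # MNase-Seq mononucleosome signal
}


@dataclass(frozen=True)
class ReadSet:
    """Aligned reads plus the library size used for depth normalization.

    ``library_size`` is the total number of uniquely mapped, deduplicated
    reads in the library — it may exceed ``len(reads)`` when only a region
    subset is loaded, but never be smaller.
    """

    reads: tuple[GenomicInterval, ...]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size < len(self.reads):
            raise ValueError(
                f"library_size ({self.library_size}) smaller than read count "
                f"({len(self.reads)})"
            )

    @classmethod
    def from_reads(cls, reads: Sequence[GenomicInterval], library_size: int | None = None):
        reads = tuple(reads)
        return cls(reads, library_size if library_size is not None else len(reads))


def remove_duplicates(reads: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Keep at most one read per (chrom, start, strand), first wins.

    Reads sharing a start position but mapped to opposite strands are both
    retained — they are independent fragments, not PCR duplicates.
    """
    seen: set[tuple[str, int, str]] = set()
    kept: list[GenomicInterval] = []
    for r in reads:
        if r.strand is None:
            raise ValueError("duplicate removal requires stranded reads")
        key = (r.chrom, r.start, r.strand)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return kept


def extend_reads(reads: Sequence[GenomicInterval], length_bp: int) -> list[GenomicInterval]:
    """Extend each read from its 5' end to ``length_bp`` in the strand
    direction (e.g. 50 nt MNase reads to the 147 bp of a mononucleosome),
    clipping at position 0."""
    if length_bp <= 0:
        raise ValueError(f"extension length must be positive, got {length_bp}")
    out: list[GenomicInterval] = []
    for r in reads:
        if r.strand is None:
            raise ValueError("read extension requires stranded reads")
        if length_bp < r.length:
            raise ValueError(
                f"extension length {length_bp} shorter than read length {r.length}"
            )
        if r.strand == "+":
            start, end = r.start, r.start + length_bp
        else:
            start, end = max(0, r.end - length_bp), r.end
        out.append(GenomicInterval(r.chrom, start, end, r.score, r.name, r.strand))
    return out


def windowed_signal(
    readset: ReadSet,
    windows: Sequence[GenomicInterval],
    halfwidth_bp: int,
    mode: str = "coverage",
) -> np.ndarray:
    """Depth-normalized signal in a ``center +/- halfwidth`` window per peak.

    For window width ``W = 2*halfwidth + 1`` (clipped at the chromosome
    start) centered on each interval's midpoint::

        signal = (read-bases overlapping the window / W) / (library_size / 1e8)

    ``mode='fiveprime'`` counts read 5' ends inside the window instead of
    overlapping bases.
    """
    if halfwidth_bp <= 0:
        raise ValueError("halfwidth must be positive")
    if readset.library_size <= 0:
        raise ValueError("library size must be positive")
    if mode not in ("coverage", "fiveprime"):
        raise ValueError(f"unknown mode {mode!r}")

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in readset.reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    starts = {c: np.array([r.start for r in rs]) for c, rs in by_chrom.items()}
    ends = {c: np.array([r.end for r in rs]) for c, rs in by_chrom.items()}
    if mode == "fiveprime":
        five = {
            c: np.array(
                [r.start if r.strand == "+" else r.end - 1 for r in rs]
            )
            for c, rs in by_chrom.items()
        }

    depth_factor = readset.library_size / LIBRARY_SCALE
    values = np.zeros(len(windows))
    for i, w in enumerate(windows):
        center = w.center
        lo = max(0, center - halfwidth_bp)
        hi = center + halfwidth_bp + 1
        width = hi - lo
        if w.chrom not in by_chrom:
            continue
        if mode == "coverage":
            ov = np.minimum(ends[w.chrom], hi) - np.maximum(starts[w.chrom], lo)
            total = ov[ov > 0].sum()
        else:
            p = five[w.chrom]
            total = int(((p >= lo) & (p < hi)).sum())
        values[i] = (total / width) / depth_factor
    return values


def read_reads_bed(path: str | Path, library_size: int | None = None) -> ReadSet:
    """Load reads from a BED6 file; library size defaults to the read count."""
    reads = read_bed(path)
    for i, r in enumerate(reads):
        if r.strand is None:
            raise ValueError(f"{path}: read {i} lacks a strand")
    return ReadSet.from_reads(reads, library_size)


def read_reads_sam(path: str | Path, library_size: int | None = None) -> ReadSet:
    """Load mapped reads from SAM/BAM (requires pysam); unmapped and
    secondary/supplementary alignments are skipped."""
    import pysam

    reads: list[GenomicInterval] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            reads.append(
                GenomicInterval(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    name=aln.query_name,
                )
            )
    return ReadSet.from_reads(reads, library_size)


def signal_matrix_long(
    per_time_readsets: dict[float, ReadSet],
    windows: Sequence[GenomicInterval],
    halfwidth_bp: int,
    peak_ids: Sequence[str] | None = None,
    replicate: str = "rep1",
    mode: str = "coverage",
) -> pd.DataFrame:
    """Long-format signal matrix (peak_id, time, replicate, value) from one
    ReadSet per time point, all measured at the same windows."""
    if peak_ids is None:
        peak_ids = [
            w.name if w.name is not None else f"{w.chrom}:{w.start}-{w.end}"
            for w in windows
        ]
    frames = []
    for t in sorted(per_time_readsets):
        vals = windowed_signal(per_time_readsets[t], windows, halfwidth_bp, mode=mode)
        frames.append(
            pd.DataFrame(
                {"peak_id": peak_ids, "time": t, "replicate": replicate, "value": vals}
            )
        )
    return pd.concat(frames, ignore_index=True)
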