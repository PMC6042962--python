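"""Core domain types for genomic occupancy analysis.

All positional logic in the package uses a single coordinate convention:
0-based, half-open ``[start, end)`` intervals (the BED convention). Formats
with 1-based inclusive coordinates (GTF/GFF) are converted at the I/O
boundary. Coverage is held as dense per-base float vectors per chromosome;
synthetic genomes are at most a few megabases, so dense storage keeps the
smoothing, ratio and profile code simple and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def distance_to_point(self, chrom: str, pos: int) -> float:
        """Distance from this interval to a point; 0 if the point is inside,
        ``inf`` if on another chromosome."""
        if chrom != self.chrom:
            return float("inf")
        if self.start <= pos < self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - (self.end - 1)))


#: Biotypes the pipeline distinguishes; anything else maps to "other".
BIOTYPES = ("protein_coding", "tRNA", "rRNA", "other")
POLYMERASES = ("PolII", "PolIII", "other")


def polymerase_for_biotype(biotype: str) -> str:
    """Default polymerase class for a biotype.

    Protein-coding genes are Pol II transcribed, tRNAs Pol III, rRNAs fall
    in the remaining class (Pol I); unknown biotypes are "other".
    """
    return {"protein_coding": "PolII", "tRNA": "PolIII"}.get(biotype, "other")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its interval, biotype and polymerase class.

    The transcription start site (TSS) is the 5' base of the interval:
    ``start`` on the + strand and ``end - 1`` on the - strand (the
    interval's last base; the convention for the minus strand). The
    transcription end site (TES) is the opposite terminus.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"
    polymerase: str = "PolII"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
        if self.polymerase not in POLYMERASES:
            raise ValueError(
                f"gene {self.gene_id}: unknown polymerase {self.polymerase!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


class CoverageTrack:
    """Dense per-base signal for one sample, keyed by chromosome.

    Values must be non-negative. ``total_signal`` is always recomputed from
    the stored vectors, so it cannot drift from the data.
    """

    def __init__(self, sample_id: str, values: Mapping[str, np.ndarray]):
        self.sample_id = sample_id
        self.values: dict[str, np.ndarray] = {}
        for chrom, vec in values.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{sample_id}/{chrom}: coverage must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"{sample_id}/{chrom}: negative coverage values")
            self.values[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    @property
    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def scaled(self, factor: float, sample_id: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            sample_id or self.sample_id,
            {c: v * factor for c, v in self.values.items()},
        )

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.values

    def __repr__(self) -> str:
        return (
            f"CoverageTrack({self.sample_id!r}, chroms={self.chroms}, "
            f"total={self.total_signal:.4g})"
        )


@dataclass
class Peak:
    interval: GenomicInterval
    score: float  # mean fold-change over the interval


@dataclass
class PeakSet:
    """Ordered, per-chromosome disjoint peaks with fold-change scores."""

    peaks: list[Peak] = field(default_factory=list)
    source_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, min_gap: int = 0) -> None:
        """Check sortedness and disjointness; with ``min_gap`` also that
        every same-chromosome adjacent pair is at least that far apart."""
        for prev, cur in zip(self.peaks, self.peaks[1:]):
            a, b = prev.interval, cur.interval
            if (a.chrom, a.start) > (b.chrom, b.start):
                raise ValueError(f"peaks not sorted: {a} before {b}")
            if a.chrom == b.chrom:
                gap = b.start - a.end
                if gap < 0:
                    raise ValueError(f"overlapping peaks: {a} and {b}")
                if gap < min_gap:
                    raise ValueError(
                        f"adjacent peaks {a} and {b} closer than {min_gap}"
                    )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    @property
    def total_bases(self) -> int:
        return sum(p.interval.length for p in self.peaks)


def sort_peaks(peaks: list[Peak]) -> list[Peak]:
    return sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
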