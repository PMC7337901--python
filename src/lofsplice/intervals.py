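"""Shared genomic data model.

Every coordinate in this package is 0-based, half-open (BED convention).
Formats that use other conventions (GTF: 1-based, closed) are converted at
the I/O boundary, never downstream.  Chromosome names are normalised by
stripping an optional ``chr`` prefix so UCSC- and ENSEMBL-style inputs mix
freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

STRANDS = {"+", "-", "."}


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix (``chr1`` -> ``1``)."""
    return chrom[3:] if chrom.lower().startswith("chr") and len(chrom) > 3 else chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with strand.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name (``chr`` prefix stripped on construction).
    start : int
        0-based inclusive start; must be >= 0.
    end : int
        Exclusive end; must be > ``start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        """True if the two intervals share >= 1 base (same chrom; same strand
        if ``stranded``)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def distance(self, other: "GenomicInterval") -> int:
        """Gap in bases between non-overlapping intervals; 0 when they touch
        or overlap.  Infinite across chromosomes."""
        if self.chrom != other.chrom:
            return int(1e18)
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end, other.start - self.end, 0)


@dataclass(frozen=True)
class ScoredInterval:
    """An interval carrying a real-valued per-base score (e.g. phyloP).

    phyloP scores are signed: 0 is neutral, > 1 highly conserved, negative
    values mark accelerated evolution — so no sign constraint, only
    finiteness.
    """

    interval: GenomicInterval
    score: float

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValueError(f"score must be finite, got {self.score}")


@dataclass
class TranscriptModel:
    """A transcript as an ordered exon chain with optional CDS.

    Exons are stored sorted by genomic coordinate (left to right regardless
    of strand) and must be non-overlapping and share chrom/strand.  ``tags``
    carries transcript-type labels (``retained_intron``,
    ``nonsense_mediated_decay``, ``cds_end_NF`` ...) used for filtering.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] | None = None
    tags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        chroms = {iv.chrom for iv in self.exons}
        strands = {iv.strand for iv in self.exons}
        if self.cds:
            self.cds = sorted(self.cds, key=lambda iv: iv.start)
            chroms |= {iv.chrom for iv in self.cds}
            strands |= {iv.strand for iv in self.cds}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: all intervals must share chrom and strand"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint from first exon start to last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, left to right."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out
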