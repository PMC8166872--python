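"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open. GFF3 input
(1-based, inclusive) is converted at parse time; BED input is used as-is.
"""
from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded). Strand is
    carried through for reporting but plays no role in pairing or
    coverage computation.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.end < self.start:
            raise ValueError(f"end < start: {self!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Number of bases strictly between the two intervals.

        0 for abutting or overlapping intervals on the same chromosome.
        """
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        return max(other.start - self.end, self.start - other.end, 0)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )
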