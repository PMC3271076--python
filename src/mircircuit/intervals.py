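"""Genomic intervals and sequence-level primitives.

All coordinates in this package are 0-based half-open (BED convention).
Printed 1-based inclusive spans, common in journal text, convert by
``start - 1`` on the start only; loaders expose a ``one_based_inclusive``
flag for tables written that way.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_STRANDS = ("+", "-")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome (or contig/locus) identifier.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; ``end - start`` is the width in bases.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @classmethod
    def from_one_based_inclusive(
        cls, chrom: str, start: int, end: int, strand: str = "+"
    ) -> "GenomicInterval":
        """Build from a printed 1-based inclusive span (start-1 conversion)."""
        return cls(chrom, start - 1, end, strand)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome sequence, stored uppercase over {A,C,G,T,N}."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_sequence(genome: dict, interval: GenomicInterval) -> str:
    """Extract the interval's sequence; minus strand returns the reverse complement.

    ``genome`` maps chromosome id to :class:`GenomeSequence` (or plain string).
    """
    try:
        record = genome[interval.chrom]
    except KeyError:
        raise KeyError(f"unknown chromosome {interval.chrom!r}") from None
    seq = record.sequence if isinstance(record, GenomeSequence) else record
    if interval.end > len(seq):
        raise ValueError(
            f"interval {interval} out of bounds for {interval.chrom} (length {len(seq)})"
        )
    sub = seq[interval.start : interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub
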