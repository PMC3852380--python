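"""Core genomic coordinate types.

All coordinates in this package are 0-based, half-open ``[start, end)``,
the native BED convention. Inputs in 1-based inclusive conventions must be
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name; non-empty.
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        Exclusive end, ``> start``.
    strand : str
        One of ``'+'``, ``'-'``, or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint (floor of the arithmetic mean of start and end)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site.

    The TSS is the first transcribed base: ``interval.start`` on the plus
    strand, ``interval.end - 1`` on the minus strand.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', "
                f"got {self.interval.strand!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class BindingRegion:
    """A merged binding region with cell-line support.

    ``support`` is the set of distinct cell lines that contributed at least
    one peak; ``n_peaks`` the number of source peaks absorbed by the merge.
    """

    br_id: str
    interval: GenomicInterval
    support: frozenset = field(default_factory=frozenset)
    n_peaks: int = 0

    def __post_init__(self) -> None:
        if not self.support:
            raise ValueError(f"{self.br_id}: support must be non-empty")
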