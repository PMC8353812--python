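"""Genomic interval and transcript-model primitives.

Coordinates are 1-based, fully closed (GTF convention) throughout the
public API; any half-open arithmetic is internal to a function.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval [start, end] on one chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 base on the same chromosome
        (strand is not compared)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """One transcript as an ordered exon chain on a genome.

    Exons are stored sorted by start coordinate and must be pairwise
    disjoint with at least a 1-bp gap between consecutive exons; all share
    the transcript's chromosome and strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "unknown"

    _BIOTYPES = {"mRNA", "ncRNA", "pseudogene", "miscRNA", "unknown"}

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.biotype not in self._BIOTYPES:
            raise ValueError(f"{self.transcript_id}: bad biotype {self.biotype!r}")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        prev_end = -1  # first exon may start at position 1
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon {ex} disagrees with transcript "
                    f"chrom/strand {self.chrom}{self.strand}"
                )
            if ex.start <= prev_end + 1:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or abut at {ex.start}"
                )
            prev_end = ex.end

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        """Genomic span from the first exon start to the last exon end."""
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        """Total exonic length in bp."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def intron_chain(t: TranscriptModel) -> list[GenomicInterval]:
    """Maximal gaps between consecutive exons of ``t``.

    Empty for single-exon transcripts; each intron lies strictly between
    its flanking exons.
    """
    introns = []
    for left, right in zip(t.exons, t.exons[1:]):
        introns.append(
            GenomicInterval(t.chrom, left.end + 1, right.start - 1, t.strand)
        )
    return introns
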