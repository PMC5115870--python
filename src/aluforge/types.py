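"""Core domain types shared across the pipeline.

All genomic intervals are stored 0-based half-open internally.  File I/O
converts at the boundary: GTF is read/written 1-based inclusive, BED and
RepeatMasker-derived tables 0-based half-open (RepeatMasker ``.out`` files
themselves are 1-based inclusive and converted on parsing).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"

    @property
    def opposite(self) -> "Strand":
        return Strand.MINUS if self is Strand.PLUS else Strand.PLUS


def as_strand(value: "str | Strand") -> Strand:
    if isinstance(value, Strand):
        return value
    return Strand(value)


@dataclass(frozen=True)
class AluElement:
    """A repeat-annotation interval (one Alu copy in the genome).

    ``milli_div`` is the element's divergence from the repeat consensus in
    substitutions per 1000 nt, as reported in the RepeatMasker table; it is
    used as a proxy for the element's evolutionary age.
    """

    chrom: str
    start: int
    end: int
    strand: Strand
    family: str
    milli_div: int
    element_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.milli_div < 0:
            raise ValueError("milli_div must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExonRecord:
    """An exon call, either predicted from RNA-seq or taken from annotation.

    ``junction_support_left``/``_right`` count junction-spanning reads at the
    genomic-left and genomic-right boundary respectively.
    """

    chrom: str
    start: int
    end: int
    strand: Strand
    source: str = "predicted"  # "predicted" | "annotated"
    junction_support_left: int = 0
    junction_support_right: int = 0
    multi_exon: bool = True
    exon_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.junction_support_left < 0 or self.junction_support_right < 0:
            raise ValueError("junction support counts must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def junction_support_total(self) -> int:
        return self.junction_support_left + self.junction_support_right

    # Splice-site anchor bases in transcript orientation: the 3'SS (acceptor)
    # anchor is the first exonic base, the 5'SS (donor) anchor the last.
    @property
    def acceptor_pos(self) -> int:
        return self.start if self.strand is Strand.PLUS else self.end - 1

    @property
    def donor_pos(self) -> int:
        return self.end - 1 if self.strand is Strand.PLUS else self.start


class SitesInAlu(str, Enum):
    FIVE_PRIME = "5'SS"
    THREE_PRIME = "3'SS"
    BOTH = "both"


class AnnotationStatus(str, Enum):
    CRYPTIC = "cryptic"
    ALTERNATIVE = "alternative"
    CONSTITUTIVE = "constitutive"


@dataclass
class AluExon:
    """An exon with one or both splice sites inside an antisense Alu element."""

    exon: ExonRecord
    alu: AluElement
    sites_in_alu: SitesInAlu
    host_gene: str
    annotation_status: Optional[AnnotationStatus] = None

    @property
    def length(self) -> int:
        return self.exon.length


@dataclass(frozen=True)
class GeneModel:
    """A flattened single-isoform gene model (one exon chain per gene)."""

    gene_id: str
    chrom: str
    strand: Strand
    exons: tuple  # ((start, end), ...) sorted by genomic start
    cds_start: Optional[int] = None  # transcript coordinate of the start codon
    cds_end: Optional[int] = None    # transcript coordinate one past the stop

    def __post_init__(self):
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"invalid exon [{s}, {e}) in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"overlapping/unsorted exons in {self.gene_id}")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def exons_transcript_order(self) -> list:
        """Exons ordered 5' -> 3' along the transcript."""
        return list(self.exons) if self.strand is Strand.PLUS else list(self.exons)[::-1]

    def transcript_pos(self, genomic_pos: int) -> Optional[int]:
        """Map a genomic position to a transcript coordinate (None if intronic)."""
        offset = 0
        for s, e in self.exons_transcript_order():
            if s <= genomic_pos < e:
                if self.strand is Strand.PLUS:
                    return offset + (genomic_pos - s)
                return offset + (e - 1 - genomic_pos)
            offset += e - s
        return None

    def transcript_sequence(self, genome: dict) -> str:
        """Spliced transcript sequence (5'->3') from a chrom -> sequence dict."""
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[s:e] for s, e in self.exons]
        mrna = "".join(parts)
        if self.strand is Strand.MINUS:
            mrna = reverse_complement(mrna)
        return mrna.upper()

    def junction_offsets(self) -> list:
        """Transcript coordinates of exon-exon junctions (first base after each)."""
        out, offset = [], 0
        order = self.exons_transcript_order()
        for s, e in order[:-1]:
            offset += e - s
            out.append(offset)
        return out


@dataclass(frozen=True)
class DivergenceGroup:
    group_index: int
    lower: int  # inclusive, substitutions per 1000 nt
    upper: int  # inclusive


# Divergence bins used to stratify Alu-exons into five age groups.
DEFAULT_DIVERGENCE_GROUPS = (
    DivergenceGroup(1, 23, 99),
    DivergenceGroup(2, 100, 121),
    DivergenceGroup(3, 122, 146),
    DivergenceGroup(4, 147, 168),
    DivergenceGroup(5, 169, 269),
)


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open interval overlap of >= 1 nt."""
    return a_start < b_end and b_start < a_end


def reverse_complement(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())
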