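"""Readers and writers for the standard interchange formats of the pipeline.

Coordinate conventions at the file boundary:

* RepeatMasker ``.out`` tables: 1-based inclusive, converted on read.
* GTF: 1-based inclusive.
* BED: 0-based half-open (matches the internal convention).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, TextIO, Union

import pandas as pd

from .types import (
    AluElement,
    AnnotationStatus,
    ExonRecord,
    GeneModel,
    Strand,
    as_strand,
)

PathOrStream = Union[str, Path, TextIO]


def _open_text(source: PathOrStream):
    if isinstance(source, (str, Path)):
        return open(source), True
    return source, False


# ---------------------------------------------------------------------------
# RepeatMasker .out tables
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query          "
    " matching repeat       position in repeat\n"
    "score   div. del. ins.  sequence  begin    end      (left)   "
    " repeat   class/family begin end  (left)  ID\n"
    "\n"
)


def read_repeatmasker(
    source: PathOrStream, alu_only: bool = True
) -> List[AluElement]:
    """Parse a RepeatMasker ``.out``-style table into AluElement records.

    Expects the usual three header lines (tolerated but not required),
    whitespace-separated columns, percent-divergence in column 2 (converted
    to substitutions per 1000 nt) and strand given as ``+`` or ``C``.  With
    ``alu_only`` (default) only rows whose repeat name starts with ``Alu``
    are kept.  Malformed rows raise with the offending line number.
    """
    stream, own = _open_text(source)
    elements: List[AluElement] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            fields = line.split()
            if not fields:
                continue
            if fields[0] in {"SW", "score"}:  # header lines
                continue
            try:
                perc_div = float(fields[1])
                chrom = fields[4]
                start1 = int(fields[5])
                end1 = int(fields[6])
                strand = Strand.MINUS if fields[8] == "C" else Strand(fields[8])
                family = fields[9]
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"malformed RepeatMasker row at line {lineno}: {line.rstrip()!r}"
                ) from exc
            if alu_only and not family.startswith("Alu"):
                continue
            elements.append(
                AluElement(
                    chrom=chrom,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    family=family,
                    milli_div=round(perc_div * 10),
                    element_id=fields[14] if len(fields) > 14 else f"rm{lineno}",
                )
            )
    finally:
        if own:
            stream.close()
    return elements


def write_repeatmasker(elements: Iterable[AluElement], path: PathOrStream) -> None:
    stream, own = (open(path, "w"), True) if isinstance(path, (str, Path)) else (path, False)
    try:
        stream.write(_RM_HEADER)
        for i, el in enumerate(elements, start=1):
            strand = "C" if el.strand is Strand.MINUS else "+"
            stream.write(
                f"  463  {el.milli_div / 10:5.1f}  0.0  0.0  {el.chrom}  "
                f"{el.start + 1}  {el.end}  (0)  {strand}  {el.family}  "
                f"SINE/Alu  1  {el.length}  (0)  {el.element_id or i}\n"
            )
    finally:
        if own:
            stream.close()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Load a FASTA file into a chrom -> uppercase sequence dict."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: Dict[str, str], path: Union[str, Path]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF (one flattened transcript per gene, with optional CDS features)
# ---------------------------------------------------------------------------

def write_gtf(genes: Iterable[GeneModel], genome_lengths: Optional[dict], path: PathOrStream) -> None:
    """Write gene models as GTF: one transcript per gene, exon + CDS features."""
    stream, own = (open(path, "w"), True) if isinstance(path, (str, Path)) else (path, False)
    try:
        for gene in genes:
            tid = f"{gene.gene_id}.t1"
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
            base = [gene.chrom, "aluforge", None, None, None, ".", gene.strand.value, "."]

            def line(feature, start0, end0, frame="."):
                f = list(base)
                f[2], f[3], f[4], f[7] = feature, str(start0 + 1), str(end0), frame
                return "\t".join(f) + "\t" + attrs + "\n"

            stream.write(line("transcript", gene.start, gene.end))
            for s, e in gene.exons:
                stream.write(line("exon", s, e))
            for s, e in _cds_genomic_intervals(gene):
                stream.write(line("CDS", s, e))
    finally:
        if own:
            stream.close()


def _cds_genomic_intervals(gene: GeneModel) -> list:
    """Genomic intervals covered by the CDS (from transcript-coord bounds)."""
    if gene.cds_start is None or gene.cds_end is None:
        return []
    out = []
    offset = 0
    for s, e in gene.exons_transcript_order():
        length = e - s
        lo = max(gene.cds_start, offset)
        hi = min(gene.cds_end, offset + length)
        if lo < hi:
            if gene.strand is Strand.PLUS:
                out.append((s + (lo - offset), s + (hi - offset)))
            else:
                out.append((e - (hi - offset), e - (lo - offset)))
        offset += length
    return sorted(out)


def read_gtf(path: Union[str, Path]) -> List[GeneModel]:
    """Read a GTF written by :func:`write_gtf` back into gene models."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    genes: List[GeneModel] = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        strand = as_strand(sub["Strand"].iloc[0])
        chrom = sub["Chromosome"].iloc[0]
        exon_rows = sub[sub["Feature"] == "exon"]
        exons = tuple(
            sorted((int(r.Start), int(r.End)) for r in exon_rows.itertuples())
        )
        model = GeneModel(gene_id=gene_id, chrom=str(chrom), strand=strand, exons=exons)
        cds_rows = sub[sub["Feature"] == "CDS"]
        if len(cds_rows):
            cds_iv = sorted((int(r.Start), int(r.End)) for r in cds_rows.itertuples())
            if strand is Strand.PLUS:
                cds_start = model.transcript_pos(cds_iv[0][0])
                cds_end = model.transcript_pos(cds_iv[-1][1] - 1) + 1
            else:
                cds_start = model.transcript_pos(cds_iv[-1][1] - 1)
                cds_end = model.transcript_pos(cds_iv[0][0]) + 1
            model = GeneModel(
                gene_id=gene_id, chrom=str(chrom), strand=strand, exons=exons,
                cds_start=cds_start, cds_end=cds_end,
            )
        genes.append(model)
    return genes


# ---------------------------------------------------------------------------
# BED (exon calls; BED6 plus junction-support and flag columns)
# ---------------------------------------------------------------------------

_BED_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "junction_support_left", "junction_support_right", "multi_exon",
]


def write_exon_bed(exons: Iterable[ExonRecord], path: PathOrStream) -> None:
    rows = [
        {
            "chrom": x.chrom, "start": x.start, "end": x.end,
            "name": x.exon_id or f"exon_{i}", "score": 0, "strand": x.strand.value,
            "junction_support_left": x.junction_support_left,
            "junction_support_right": x.junction_support_right,
            "multi_exon": int(x.multi_exon),
        }
        for i, x in enumerate(exons)
    ]
    pd.DataFrame(rows, columns=_BED_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_exon_bed(path: PathOrStream, source: str = "predicted") -> List[ExonRecord]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLUMNS)
    return [
        ExonRecord(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            strand=as_strand(r.strand), source=source,
            junction_support_left=int(r.junction_support_left),
            junction_support_right=int(r.junction_support_right),
            multi_exon=bool(r.multi_exon), exon_id=str(r.name),
        )
        for r in df.itertuples()
    ]


def write_alu_exon_bed(alu_exons, path: PathOrStream) -> None:
    """BED6+ output of discovered Alu-exons with status and host-gene columns."""
    rows = [
        {
            "chrom": ax.exon.chrom, "start": ax.exon.start, "end": ax.exon.end,
            "name": ax.exon.exon_id or f"alu_exon_{i}", "score": 0,
            "strand": ax.exon.strand.value,
            "sites_in_alu": ax.sites_in_alu.value,
            "status": ax.annotation_status.value if ax.annotation_status else ".",
            "host_gene": ax.host_gene,
            "alu_id": ax.alu.element_id,
        }
        for i, ax in enumerate(alu_exons)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
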