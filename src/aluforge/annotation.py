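"""Alu-exon discovery and annotation-status classification.

The discovery chain: parse the repeat table, restrict to elements that are
intronic and antisense to a host gene, then call Alu-exons from predicted
exons whose acceptor and/or donor boundary base falls inside such an element
and which carry junction-read support (or appear in an external whitelist).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .types import (
    AluElement,
    AluExon,
    AnnotationStatus,
    DEFAULT_DIVERGENCE_GROUPS,
    ExonRecord,
    GeneModel,
    SitesInAlu,
    overlaps,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HostedAlu:
    """An Alu element intronic and antisense to one particular host gene."""

    alu: AluElement
    host_gene: str


def antisense_alus(
    alus: Iterable[AluElement], genes: Sequence[GeneModel]
) -> List[HostedAlu]:
    """Elements fully inside an intron of a gene on the opposite strand.

    An element intronic to qualifying genes on both strands is retained once
    per host; sense-orientation and intergenic elements are dropped.
    """
    out: List[HostedAlu] = []
    for alu in alus:
        for gene in genes:
            if gene.chrom != alu.chrom or gene.strand == alu.strand:
                continue
            for istart, iend in gene.introns():
                if istart <= alu.start and alu.end <= iend:
                    out.append(HostedAlu(alu=alu, host_gene=gene.gene_id))
                    break
    return out


def sites_in_alu(exon: ExonRecord, alu: AluElement) -> Optional[SitesInAlu]:
    """Which splice-site anchor bases of the exon fall inside the element.

    The 3'SS anchor is the first exonic base in transcript orientation, the
    5'SS anchor the last; either lying in [alu.start, alu.end) qualifies.
    """
    acc = alu.start <= exon.acceptor_pos < alu.end
    don = alu.start <= exon.donor_pos < alu.end
    if acc and don:
        return SitesInAlu.BOTH
    if acc:
        return SitesInAlu.THREE_PRIME
    if don:
        return SitesInAlu.FIVE_PRIME
    return None


WhitelistKey = Tuple[str, int, int, str]


def _whitelist_key(exon: ExonRecord) -> WhitelistKey:
    return (exon.chrom, exon.start, exon.end, exon.strand.value)


def call_alu_exons(
    predictions: Iterable[ExonRecord],
    hosted: Sequence[HostedAlu],
    whitelist: Optional[Set[WhitelistKey]] = None,
    min_junction_reads: int = 1,
) -> List[AluExon]:
    """Call Alu-exons from predicted exons against antisense elements.

    A prediction becomes an Alu-exon when one or both of its splice-site
    anchors lie inside an antisense element hosted by a gene on the exon's
    own strand, it belongs to a multi-exon transcript, and it either carries
    at least ``min_junction_reads`` junction-spanning reads or appears in the
    external ``whitelist`` (coordinates previously established elsewhere).
    When several elements contain a site, the one containing the acceptor
    wins, then the leftmost element.
    """
    whitelist = whitelist or set()
    by_gene: Dict[str, List[HostedAlu]] = {}
    for h in hosted:
        by_gene.setdefault(h.host_gene, []).append(h)
    gene_strands = {}
    for h in hosted:
        gene_strands.setdefault(h.host_gene, set())

    out: List[AluExon] = []
    for exon in predictions:
        candidates = []
        for h in hosted:
            if h.alu.chrom != exon.chrom or h.alu.strand == exon.strand:
                # the element must be antisense to the exon's (host gene's)
                # strand; same-strand elements would be sense exonisation
                continue
            sites = sites_in_alu(exon, h.alu)
            if sites is not None:
                candidates.append((h, sites))
        if not candidates:
            continue
        supported = exon.multi_exon and exon.junction_support_total >= min_junction_reads
        if not supported and _whitelist_key(exon) not in whitelist:
            logger.debug("dropping unsupported exon %s", exon)
            continue
        candidates.sort(
            key=lambda c: (c[1] is SitesInAlu.FIVE_PRIME, c[0].alu.start)
        )
        host, sites = candidates[0]
        out.append(
            AluExon(exon=exon, alu=host.alu, sites_in_alu=sites, host_gene=host.host_gene)
        )
    return out


def classify_annotation_status(
    alu_exons: Iterable[AluExon], reference: pd.DataFrame
) -> List[AluExon]:
    """Assign cryptic / alternative / constitutive status in place.

    ``reference`` needs columns chrom, start, end, strand, is_alternative,
    in_canonical (the alternative-event flag and canonical-transcript-set
    membership stand in for browser annotation sources).  Exons absent from
    the reference are cryptic; annotated exons flagged alternative or outside
    the canonical set are alternative; the rest are constitutive.
    """
    index = {
        (r.chrom, int(r.start), int(r.end), r.strand): (bool(r.is_alternative), bool(r.in_canonical))
        for r in reference.itertuples()
    }
    out = []
    for ax in alu_exons:
        key = (ax.exon.chrom, ax.exon.start, ax.exon.end, ax.exon.strand.value)
        if key not in index:
            ax.annotation_status = AnnotationStatus.CRYPTIC
        else:
            is_alt, canonical = index[key]
            if is_alt or not canonical:
                ax.annotation_status = AnnotationStatus.ALTERNATIVE
            else:
                ax.annotation_status = AnnotationStatus.CONSTITUTIVE
        out.append(ax)
    return out


def _interval(item) -> Tuple[str, int, int]:
    exon = getattr(item, "exon", item)
    return exon.chrom, exon.start, exon.end


def merge_nonoverlapping(items: Sequence) -> List:
    """Collapse overlapping exons, keeping the largest (leftmost on ties).

    Accepts AluExon or ExonRecord items; survivors are pairwise
    non-overlapping and returned in genomic order.
    """
    order = sorted(
        items,
        key=lambda x: (-(_interval(x)[2] - _interval(x)[1]), _interval(x)[1], _interval(x)[2]),
    )
    kept: List = []
    for item in order:
        chrom, s, e = _interval(item)
        if any(
            c == chrom and overlaps(s, e, ks, ke)
            for c, ks, ke in map(_interval, kept)
        ):
            continue
        kept.append(item)
    kept.sort(key=_interval)
    return kept


def divergence_group(milli_div: int, groups=DEFAULT_DIVERGENCE_GROUPS) -> Optional[int]:
    """Map a substitutions-per-1000-nt value to its age-group index (or None)."""
    for g in groups:
        if g.lower <= milli_div <= g.upper:
            return g.group_index
    return None


_STATUS_PRIORITY = {
    AnnotationStatus.CONSTITUTIVE: 3,
    AnnotationStatus.ALTERNATIVE: 2,
    AnnotationStatus.CRYPTIC: 1,
}


def assign_genes(
    alu_exons: Iterable[AluExon],
    genes: Sequence[GeneModel],
    expression: Optional[pd.Series] = None,
    min_rpkm: float = 1.0,
) -> Tuple[pd.DataFrame, List[AluExon]]:
    """Per-gene Alu class from the exons falling within each gene span.

    Gene class priority: constitutive > alternative > cryptic.  With an
    ``expression`` series (gene -> RPKM) genes below ``min_rpkm`` are dropped
    from the class table.  Returns (gene table, unassigned exons).
    """
    spans = {g.gene_id: g for g in genes}
    per_gene: Dict[str, int] = {}
    unassigned: List[AluExon] = []
    for ax in alu_exons:
        gene = spans.get(ax.host_gene)
        if gene is None or not (
            gene.chrom == ax.exon.chrom
            and gene.start <= ax.exon.start
            and ax.exon.end <= gene.end
        ):
            unassigned.append(ax)
            continue
        if ax.annotation_status is None:
            continue
        prio = _STATUS_PRIORITY[ax.annotation_status]
        per_gene[ax.host_gene] = max(per_gene.get(ax.host_gene, 0), prio)
    rev = {v: k for k, v in _STATUS_PRIORITY.items()}
    rows = []
    for gene_id, prio in sorted(per_gene.items()):
        if expression is not None and expression.get(gene_id, 0.0) < min_rpkm:
            continue
        rows.append({"gene_id": gene_id, "alu_class": rev[prio].value})
    return pd.DataFrame(rows, columns=["gene_id", "alu_class"]), unassigned
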