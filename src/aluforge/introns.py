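"""Intron-retention interval construction and linkage to Alu-exons.

Retention is measured on trimmed intron intervals: introns shorter than
60 nt are ignored and the rest are shrunk by 25 nt on either side so reads
from nearby alternative splice sites do not leak into the intronic signal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .types import AluExon, GeneModel, overlaps

logger = logging.getLogger(__name__)

MIN_RAW_LENGTH = 60
TRIM_EACH_SIDE = 25

REASON_NONE = "none"
REASON_TOO_SHORT = "too_short"
REASON_CRYPTIC = "contains_cryptic_exon"
REASON_FOREIGN = "overlaps_foreign_exon"


@dataclass(frozen=True)
class IntronInterval:
    gene_id: str
    chrom: str
    raw_start: int
    raw_end: int
    start: int  # trimmed
    end: int
    flank_of: Optional[str] = None  # Alu-exon id
    side: Optional[str] = None  # "upstream" | "downstream" (transcript orientation)
    excluded_reason: str = REASON_NONE

    @property
    def retained(self) -> bool:
        return self.excluded_reason == REASON_NONE


def _make_interval(gene, raw: Tuple[int, int], cryptic: Sequence[Tuple[int, int]],
                   flank_of=None, side=None, foreign: Sequence[Tuple[int, int]] = ()) -> IntronInterval:
    s, e = raw
    reason = REASON_NONE
    if e - s < MIN_RAW_LENGTH:
        reason = REASON_TOO_SHORT
    elif any(overlaps(s, e, cs, ce) for cs, ce in cryptic):
        reason = REASON_CRYPTIC
    elif any(overlaps(s, e, fs, fe) for fs, fe in foreign):
        reason = REASON_FOREIGN
    return IntronInterval(
        gene_id=gene.gene_id, chrom=gene.chrom, raw_start=s, raw_end=e,
        start=s + TRIM_EACH_SIDE, end=e - TRIM_EACH_SIDE,
        flank_of=flank_of, side=side, excluded_reason=reason,
    )


def build_flanking_introns(
    alu_exons: Iterable[AluExon],
    genes: Dict[str, GeneModel],
    cryptic_exons: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> List[IntronInterval]:
    """The two introns flanking each Alu-exon, trimmed and filtered.

    Upstream/downstream are named in transcript orientation.  Introns
    containing any cryptic exon call (other than the Alu-exon itself, >= 1 nt
    overlap) are excluded; an Alu-exon whose host intron cannot be found is
    skipped with a log message.
    """
    cryptic = cryptic_exons or []
    out: List[IntronInterval] = []
    for ax in alu_exons:
        gene = genes[ax.host_gene]
        host = None
        for istart, iend in gene.introns():
            if istart <= ax.exon.start and ax.exon.end <= iend:
                host = (istart, iend)
                break
        if host is None:
            logger.warning("%s: Alu-exon not inside an annotated intron", ax.exon.exon_id)
            continue
        exid = ax.exon.exon_id or f"{ax.alu.element_id}_exon"
        own = (ax.exon.start, ax.exon.end)
        local_cryptic = [
            (cs, ce) for (cchrom, cs, ce) in cryptic
            if cchrom == gene.chrom and (cs, ce) != own
        ]
        left = (host[0], ax.exon.start)
        right = (ax.exon.end, host[1])
        if gene.strand.value == "+":
            sides = (("upstream", left), ("downstream", right))
        else:
            sides = (("upstream", right), ("downstream", left))
        for side, raw in sides:
            out.append(_make_interval(gene, raw, local_cryptic, flank_of=exid, side=side))
    return out


def build_all_introns(
    genes: Sequence[GeneModel],
    cryptic_by_gene: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
) -> List[IntronInterval]:
    """Genome-wide intron intervals: per-gene exon-chain gaps, filtered.

    Cryptic Alu-exon calls are counted as exons of their host gene (splitting
    the gap they fall in); gaps overlapping an annotated exon of another gene
    are excluded.  The same length and trimming rules apply.
    """
    cryptic_by_gene = cryptic_by_gene or {}
    exon_index: List[Tuple[str, str, int, int]] = [
        (g.chrom, g.gene_id, s, e) for g in genes for s, e in g.exons
    ]
    out: List[IntronInterval] = []
    for gene in genes:
        exons = sorted(list(gene.exons) + list(cryptic_by_gene.get(gene.gene_id, [])))
        foreign = [
            (s, e) for chrom, gid, s, e in exon_index
            if chrom == gene.chrom and gid != gene.gene_id
        ]
        for i in range(len(exons) - 1):
            raw = (exons[i][1], exons[i + 1][0])
            if raw[1] <= raw[0]:
                continue
            out.append(_make_interval(gene, raw, cryptic=[], foreign=foreign))
    return out


_INTRON_FEATURE_RE = re.compile(r"^(?P<alu>.+)_intron_(?P<side>upstream|downstream)$")

STATUS_NONE = "none"
STATUS_UPSTREAM = "upstream"
STATUS_DOWNSTREAM = "downstream"
STATUS_BOTH = "both"


def link_retention(
    intron_results: pd.DataFrame,
    padj_threshold: float = 0.01,
    excluded: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-Alu-exon retention status from flanking-intron usage results.

    ``intron_results`` rows carry feature ids of the form
    ``<alu_id>_intron_<side>`` plus an adjusted p column.  A flank is
    retained when padj < threshold and (when a log2fc column is present) its
    usage moved upward — a significant *drop* of the intronic share is a
    denominator effect of exon inclusion, not retention.  Flanks listed in
    ``excluded`` (dropped at interval construction) count as not retained
    and are flagged.
    """
    excluded = set(excluded or ())
    per_alu: Dict[str, Dict[str, bool]] = {}
    flagged: Dict[str, bool] = {}
    for row in intron_results.itertuples():
        m = _INTRON_FEATURE_RE.match(str(row.feature_id))
        if not m:
            continue
        alu, side = m.group("alu"), m.group("side")
        if row.feature_id in excluded:
            per_alu.setdefault(alu, {})[side] = False
            flagged[alu] = True
            continue
        padj = getattr(row, "padj", float("nan"))
        lfc = getattr(row, "log2fc", 1.0)
        hit = bool(padj == padj and padj < padj_threshold and lfc > 0)
        per_alu.setdefault(alu, {})[side] = hit
    rows = []
    for alu, sides in sorted(per_alu.items()):
        up = sides.get("upstream", False)
        down = sides.get("downstream", False)
        status = {
            (True, True): STATUS_BOTH,
            (True, False): STATUS_UPSTREAM,
            (False, True): STATUS_DOWNSTREAM,
            (False, False): STATUS_NONE,
        }[(up, down)]
        rows.append({
            "alu_exon_id": alu, "retention": status,
            "flank_excluded": flagged.get(alu, False),
        })
    return pd.DataFrame(rows, columns=["alu_exon_id", "retention", "flank_excluded"])


def write_intron_bed(introns: Sequence[IntronInterval], path) -> None:
    rows = [
        {
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "name": f"{iv.gene_id}|{iv.flank_of or '.'}|{iv.side or '.'}",
            "score": 0, "strand": ".", "reason": iv.excluded_reason,
        }
        for iv in introns
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
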