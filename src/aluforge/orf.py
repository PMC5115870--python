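"""Coding-impact prediction for exons inserted into transcript models.

The reading frame of an inserted exon is determined from the exonic distance
between the annotated start codon and the exon start.  An in-frame stop
within the exon makes it PTC+; otherwise a length not divisible by three
makes it a potential frame-shift.  For PTC+ exons the distance from the stop
to the next downstream exon-exon junction feeds the 55-nt rule of
nonsense-mediated decay target prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .synthetic import STOP_CODONS
from .types import AluExon, GeneModel, Strand

#: minimal stop-to-junction distance for efficient decay-pathway recruitment
NMD_DISTANCE_THRESHOLD = 55

IMPACT_OUTSIDE = "outside_CDS"
IMPACT_PTC = "PTC_plus"
IMPACT_FRAMESHIFT = "frameshift"
IMPACT_IN_FRAME = "in_frame"

PRED_SENSITIVE = "sensitive-if >= 55 nt"
PRED_REFRACTORY = "refractory-if < 55 nt"
PRED_LAST_EXON = "last-exon"


@dataclass(frozen=True)
class PtcAnnotation:
    impact: str
    ptc_position: Optional[int] = None  # transcript coordinate of the stop's first base
    distance_to_next_junction: Optional[int] = None
    downstream_junction_count: int = 0
    nmd_rule_prediction: Optional[str] = None
    noncoding: bool = False

    def __post_init__(self):
        if (self.ptc_position is not None) != (self.impact == IMPACT_PTC):
            raise ValueError("ptc_position must be set exactly for PTC_plus calls")


def insert_exon(
    transcript: GeneModel, exon: Tuple[int, int]
) -> Tuple[int, Tuple[int, int], GeneModel]:
    """Place a (genomic) exon interval into a transcript model.

    Returns (1-based ordinal slot in transcript order, transcript-coordinate
    span, new model).  The exon must either match an annotated exon exactly
    or lie fully within an intron; partial overlap with an annotated exon is
    ambiguous and raises.  The CDS bounds of the new model are remapped so
    they still point at the annotated start/stop codons.
    """
    s, e = exon
    if exon in transcript.exons:
        new = transcript
    else:
        for istart, iend in transcript.introns():
            if istart <= s and e <= iend:
                break
        else:
            raise ValueError(
                f"exon [{s}, {e}) straddles an exon/intron boundary of "
                f"{transcript.gene_id}"
            )
        new_exons = tuple(sorted(list(transcript.exons) + [exon]))
        new = GeneModel(
            gene_id=transcript.gene_id, chrom=transcript.chrom,
            strand=transcript.strand, exons=new_exons,
        )
        new = _remap_cds(transcript, new)
    order = new.exons_transcript_order()
    slot = order.index((s, e)) + 1
    tstart = new.transcript_pos(s if new.strand is Strand.PLUS else e - 1)
    return slot, (tstart, tstart + (e - s)), new


def _remap_cds(old: GeneModel, new: GeneModel) -> GeneModel:
    if old.cds_start is None:
        return new
    g_start = _genomic_pos(old, old.cds_start)
    g_last = _genomic_pos(old, old.cds_end - 1)
    return GeneModel(
        gene_id=new.gene_id, chrom=new.chrom, strand=new.strand, exons=new.exons,
        cds_start=new.transcript_pos(g_start),
        cds_end=new.transcript_pos(g_last) + 1,
    )


def _genomic_pos(model: GeneModel, tpos: int) -> int:
    offset = 0
    for s, e in model.exons_transcript_order():
        if tpos < offset + (e - s):
            within = tpos - offset
            return s + within if model.strand is Strand.PLUS else e - 1 - within
        offset += e - s
    raise ValueError(f"transcript position {tpos} outside {model.gene_id}")


def classify_coding_impact(
    transcript: GeneModel, exon: Tuple[int, int], genome: Dict[str, str]
) -> Tuple[PtcAnnotation, GeneModel]:
    """Classify the coding impact of inserting ``exon`` into ``transcript``.

    Returns the annotation together with the exon-containing model (needed
    for junction distances).  An exon upstream of the start codon or
    downstream of the annotated stop is outside_CDS; exons spanning the CDS
    start are classified by the portion inside the CDS.  The in-frame stop
    scan anchors codons at the annotated start codon and counts a stop as
    inside the exon when its first base is.
    """
    slot, (tstart, tend), model = insert_exon(transcript, exon)
    if transcript.cds_start is None:
        return PtcAnnotation(impact=IMPACT_OUTSIDE, noncoding=True), model
    cds_start, cds_end = model.cds_start, model.cds_end
    if tend <= cds_start or tstart >= cds_end:
        return PtcAnnotation(impact=IMPACT_OUTSIDE), model

    mrna = model.transcript_sequence(genome)
    eff_start = max(tstart, cds_start)
    # first codon whose first base is inside the exon
    phase = (eff_start - cds_start) % 3
    first_codon = eff_start + ((3 - phase) % 3) if phase else eff_start
    for p in range(first_codon, min(tend, len(mrna) - 2), 3):
        if mrna[p:p + 3] in STOP_CODONS:
            ann = _with_distance(model, p)
            return ann, model
    if (tend - eff_start) % 3 != 0:
        return PtcAnnotation(impact=IMPACT_FRAMESHIFT), model
    return PtcAnnotation(impact=IMPACT_IN_FRAME), model


def ptc_junction_distance(
    model: GeneModel, ptc_position: int
) -> Tuple[Optional[int], int, str]:
    """(distance, downstream junction count, rule prediction) for a PTC.

    Distance runs from the first base of the stop codon to the next
    downstream exon-exon junction, exclusive; a PTC in the last exon yields
    (None, 0, last-exon).
    """
    downstream = [j for j in model.junction_offsets() if j > ptc_position]
    if not downstream:
        return None, 0, PRED_LAST_EXON
    distance = downstream[0] - ptc_position
    pred = PRED_SENSITIVE if distance >= NMD_DISTANCE_THRESHOLD else PRED_REFRACTORY
    return distance, len(downstream), pred


def _with_distance(model: GeneModel, ptc_position: int) -> PtcAnnotation:
    distance, count, pred = ptc_junction_distance(model, ptc_position)
    return PtcAnnotation(
        impact=IMPACT_PTC,
        ptc_position=ptc_position,
        distance_to_next_junction=distance,
        downstream_junction_count=count,
        nmd_rule_prediction=pred,
    )


def annotate_coding_impacts(
    alu_exons: Iterable[AluExon],
    genes: Dict[str, GeneModel],
    genome: Dict[str, str],
    require_junction_support: bool = True,
) -> List[Tuple[AluExon, Optional[PtcAnnotation]]]:
    """Coding impact for a set of discovered Alu-exons.

    With ``require_junction_support`` (the accuracy gate) only exons with
    junction-spanning reads at both boundaries are classified; others get
    None.
    """
    out = []
    for ax in alu_exons:
        if require_junction_support and (
            ax.exon.junction_support_left < 1 or ax.exon.junction_support_right < 1
        ):
            out.append((ax, None))
            continue
        ann, _ = classify_coding_impact(
            genes[ax.host_gene], (ax.exon.start, ax.exon.end), genome
        )
        out.append((ax, ann))
    return out
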