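import numpy as np
import pytest
from Bio.Seq import Seq

from aluforge import orf
from aluforge.synthetic import STOP_CODONS
from aluforge.types import GeneModel, Strand


def plus_gene(cds=(10, 310)):
    return GeneModel(
        gene_id="g", chrom="c", strand=Strand.PLUS,
        exons=((0, 100), (300, 400), (600, 700), (900, 1000)),
        cds_start=cds[0], cds_end=cds[1],
    )


class TestInsertExon:
    def test_exon_in_intron_two_becomes_exon_three(self):
        slot, (ts, te), model = orf.insert_exon(plus_gene(), (420, 460))
        assert slot == 3
        assert (ts, te) == (200, 240)
        assert len(model.exons) == 5

    def test_exon_identical_to_annotated_keeps_slot(self):
        slot, (ts, te), model = orf.insert_exon(plus_gene(), (300, 400))
        assert slot == 2
        assert (ts, te) == (100, 200)
        assert len(model.exons) == 4

    def test_exon_straddling_boundary_rejected(self):
        with pytest.raises(ValueError, match="straddles"):
            orf.insert_exon(plus_gene(), (350, 450))

    def test_minus_strand_slot_counted_from_transcript_five_prime(self):
        gene = GeneModel(
            gene_id="g", chrom="c", strand=Strand.MINUS,
            exons=((0, 100), (200, 300), (400, 500)),
        )
        slot, (ts, te), _ = orf.insert_exon(gene, (320, 360))
        # transcript order is genomic-right to genomic-left
        assert slot == 2
        assert (ts, te) == (100, 140)

    def test_cds_coordinates_shift_with_upstream_insertion(self):
        gene = plus_gene(cds=(150, 250))  # CDS starts in exon 2
        _, _, model = orf.insert_exon(gene, (120, 150))
        assert model.cds_start == gene.cds_start + 30
        assert model.cds_end == gene.cds_end + 30


def make_genome_for(gene, seq):
    return {gene.chrom: seq}


def build_sequence(rng, gene, exon, stop_free_insert):
    """Random chromosome; the inserted exon body optionally stop-free."""
    n = gene.end + 50
    seq = list("".join(rng.choice(list("ACGT"), size=n)))
    if stop_free_insert:
        body = []
        while len(body) < (exon[1] - exon[0]) + 2:
            codon = "".join(rng.choice(list("ACGT"), size=3))
            if codon not in STOP_CODONS:
                body.append(codon)
        seq[exon[0]:exon[1]] = list("".join(body))[: exon[1] - exon[0]]
    return "".join(seq)


def oracle_classify(gene, exon, genome):
    """Independent oracle: full-mRNA translation from the start codon."""
    _, (ts, te), model = orf.insert_exon(gene, exon)
    if gene.cds_start is None:
        return "outside_CDS", None
    cds_start, cds_end = model.cds_start, model.cds_end
    if te <= cds_start or ts >= cds_end:
        return "outside_CDS", None
    mrna = model.transcript_sequence(genome)
    coding = mrna[cds_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    stop_positions = [cds_start + 3 * i for i, aa in enumerate(protein) if aa == "*"]
    eff_start = max(ts, cds_start)
    in_exon = [p for p in stop_positions if eff_start <= p and ts <= p < te]
    # the first in-frame stop inside the exon, but only if the frame reaches it
    first = None
    for p in in_exon:
        if p >= eff_start:
            first = p
            break
    if first is not None:
        return "PTC_plus", first
    if (te - eff_start) % 3 != 0:
        return "frameshift", None
    return "in_frame", None


class TestCodingImpactExamples:
    def _genome(self, gene, rng, exon, stop_free=True):
        return make_genome_for(gene, build_sequence(rng, gene, exon, stop_free))

    def test_84nt_stop_free_exon_is_in_frame(self, rng):
        # exon starts at transcript offset 200, in phase 0 for cds_start 11
        gene = plus_gene(cds=(11, 311))
        exon = (420, 504)  # 84 nt
        genome = self._genome(gene, rng, exon)
        ann, _ = orf.classify_coding_impact(gene, exon, genome)
        assert ann.impact == "in_frame"

    def test_100nt_stop_free_exon_is_frameshift(self, rng):
        gene = plus_gene(cds=(11, 311))
        exon = (420, 520)
        genome = self._genome(gene, rng, exon)
        ann, _ = orf.classify_coding_impact(gene, exon, genome)
        assert ann.impact == "frameshift"

    def test_planted_in_frame_taa_yields_ptc_plus_at_offset(self, rng):
        gene = plus_gene(cds=(11, 311))
        exon = (420, 504)
        genome = self._genome(gene, rng, exon)
        seq = list(genome[gene.chrom])
        ptc_genomic = exon[0] + 9  # phase 0: codons align with the exon start
        seq[ptc_genomic:ptc_genomic + 3] = list("TAA")
        ann, _ = orf.classify_coding_impact(gene, exon, {gene.chrom: "".join(seq)})
        assert ann.impact == "PTC_plus"
        assert ann.ptc_position == 200 + 9

    def test_exon_downstream_of_stop_is_outside_cds(self, rng):
        gene = plus_gene(cds=(10, 190))
        exon = (420, 504)
        genome = self._genome(gene, rng, exon)
        ann, _ = orf.classify_coding_impact(gene, exon, genome)
        assert ann.impact == "outside_CDS"

    def test_noncoding_transcript_flagged(self, rng):
        gene = GeneModel(
            gene_id="nc", chrom="c", strand=Strand.PLUS,
            exons=((0, 100), (300, 400), (600, 700)),
        )
        genome = self._genome(gene, rng, (420, 460))
        ann, _ = orf.classify_coding_impact(gene, (420, 460), genome)
        assert ann.impact == "outside_CDS" and ann.noncoding


class TestPtcJunctionDistance:
    def test_distance_below_threshold_refractory(self):
        _, _, model = orf.insert_exon(plus_gene(), (420, 460))
        # junctions at transcript offsets 100, 200, 240, 340
        distance, count, pred = orf.ptc_junction_distance(model, 200)
        assert distance == 40
        assert pred == orf.PRED_REFRACTORY

    def test_distance_at_least_55_sensitive_with_downstream_count(self):
        _, _, model = orf.insert_exon(plus_gene(), (420, 460))
        distance, count, pred = orf.ptc_junction_distance(model, 140)
        assert distance == 60 and count == 3
        assert pred == orf.PRED_SENSITIVE

    def test_ptc_in_last_exon(self):
        model = plus_gene()
        distance, count, pred = orf.ptc_junction_distance(model, 350)
        assert distance is None and count == 0 and pred == orf.PRED_LAST_EXON


def test_agreement_with_translation_oracle_on_random_transcripts():
    """Implementation matches full-mRNA translation on 500 random models."""
    rng = np.random.default_rng(99)
    n_checked = 0
    counts = {}
    while n_checked < 500:
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        exon_starts = [0, 200, 400, 600]
        exons = tuple((s, s + int(rng.integers(60, 120))) for s in exon_starts)
        gene = GeneModel(
            gene_id="g", chrom="c", strand=strand, exons=exons,
            cds_start=int(rng.integers(0, 30)),
        )
        # pick the annotated stop from the unmodified transcript
        probe = {"c": "".join(rng.choice(list("ACGT"), size=gene.end + 100))}
        mrna = gene.transcript_sequence(probe)
        stops = [
            p for p in range(gene.cds_start, len(mrna) - 2, 3)
            if mrna[p:p + 3] in STOP_CODONS
        ]
        if not stops:
            continue
        gene = GeneModel(
            gene_id="g", chrom="c", strand=strand, exons=exons,
            cds_start=gene.cds_start, cds_end=stops[0] + 3,
        )
        intron = gene.introns()[int(rng.integers(len(gene.introns())))]
        if intron[1] - 70 <= intron[0] + 5:
            continue
        s = int(rng.integers(intron[0] + 5, intron[1] - 70))
        exon = (s, s + int(rng.integers(30, min(60, intron[1] - s - 5))))
        if rng.random() < 0.5:
            genome = {"c": build_sequence(rng, gene, exon, stop_free_insert=True)}
        else:
            genome = probe
        ann, _ = orf.classify_coding_impact(gene, exon, genome)
        expect_impact, expect_pos = oracle_classify(gene, exon, genome)
        assert ann.impact == expect_impact, (gene, exon)
        if expect_impact == "PTC_plus":
            assert ann.ptc_position == expect_pos
        counts[expect_impact] = counts.get(expect_impact, 0) + 1
        n_checked += 1
    # the random cohort must exercise every branch
    assert set(counts) >= {"PTC_plus", "in_frame", "frameshift"}


def test_constitutive_exons_of_intact_models_are_devoid_of_ptcs(small_dataset):
    """Annotated exon chains carry no internal stop within their CDS."""
    for gene in small_dataset.genes:
        mrna = gene.transcript_sequence(small_dataset.genome)
        coding = mrna[gene.cds_start:gene.cds_end - 3]
        internal = [
            coding[i:i + 3] for i in range(0, len(coding) - 2, 3)
        ]
        assert not any(c in STOP_CODONS for c in internal), gene.gene_id


def test_junction_support_gate(small_dataset):
    from aluforge import annotation

    ds = small_dataset
    hosted = annotation.antisense_alus(ds.alus, ds.genes)
    calls = annotation.call_alu_exons(ds.predicted_exons, hosted)
    genes = {g.gene_id: g for g in ds.genes}
    # force one exon to lack support on one side
    calls[0].exon = type(calls[0].exon)(
        chrom=calls[0].exon.chrom, start=calls[0].exon.start, end=calls[0].exon.end,
        strand=calls[0].exon.strand, junction_support_left=0, junction_support_right=3,
    )
    out = orf.annotate_coding_impacts(calls, genes, ds.genome, require_junction_support=True)
    assert out[0][1] is None
    out = orf.annotate_coding_impacts(calls, genes, ds.genome, require_junction_support=False)
    assert out[0][1] is not None
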