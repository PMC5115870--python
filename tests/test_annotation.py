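import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aluforge import annotation
from aluforge.types import (
    AluElement,
    AnnotationStatus,
    ExonRecord,
    GeneModel,
    SitesInAlu,
    Strand,
    overlaps,
)


def gene(gene_id="g1", strand=Strand.PLUS, chrom="chr1"):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        exons=((0, 100), (1000, 1100), (2000, 2100)),
    )


def alu(start=300, end=600, strand=Strand.MINUS, chrom="chr1", element_id="a1"):
    return AluElement(
        chrom=chrom, start=start, end=end, strand=strand,
        family="AluSx", milli_div=80, element_id=element_id,
    )


def exon(start, end, strand=Strand.PLUS, support=(1, 1), multi=True, chrom="chr1"):
    return ExonRecord(
        chrom=chrom, start=start, end=end, strand=strand,
        junction_support_left=support[0], junction_support_right=support[1],
        multi_exon=multi,
    )


class TestAntisenseAlus:
    def test_minus_alu_in_plus_gene_intron_retained(self):
        hosted = annotation.antisense_alus([alu()], [gene()])
        assert len(hosted) == 1 and hosted[0].host_gene == "g1"

    def test_sense_alu_dropped(self):
        hosted = annotation.antisense_alus([alu(strand=Strand.PLUS)], [gene()])
        assert hosted == []

    def test_intergenic_alu_dropped(self):
        hosted = annotation.antisense_alus([alu(start=5000, end=5300)], [gene()])
        assert hosted == []

    def test_exon_overlapping_alu_dropped(self):
        hosted = annotation.antisense_alus([alu(start=50, end=350)], [gene()])
        assert hosted == []

    def test_alu_between_two_opposite_genes_retained_per_host(self):
        g_plus = gene("gp", Strand.PLUS)
        g_minus = GeneModel(
            gene_id="gm", chrom="chr1", strand=Strand.MINUS,
            exons=((10, 110), (900, 1100), (1900, 2100)),
        )
        # an element antisense to one gene is sense to the other, so a single
        # element can have at most one host here; use both orientations
        hosted = annotation.antisense_alus(
            [alu(strand=Strand.MINUS, element_id="am"),
             alu(strand=Strand.PLUS, start=320, end=620, element_id="ap")],
            [g_plus, g_minus],
        )
        hosts = {(h.alu.element_id, h.host_gene) for h in hosted}
        assert hosts == {("am", "gp"), ("ap", "gm")}


class TestCallAluExons:
    def setup_method(self):
        self.hosted = annotation.antisense_alus([alu()], [gene()])

    def test_supported_exon_with_3ss_in_alu(self):
        calls = annotation.call_alu_exons([exon(500, 700, support=(2, 0))], self.hosted)
        assert len(calls) == 1
        assert calls[0].sites_in_alu is SitesInAlu.THREE_PRIME
        assert calls[0].host_gene == "g1"

    def test_both_sites_in_alu(self):
        calls = annotation.call_alu_exons([exon(400, 550)], self.hosted)
        assert calls[0].sites_in_alu is SitesInAlu.BOTH

    def test_unsupported_exon_dropped(self):
        calls = annotation.call_alu_exons([exon(500, 700, support=(0, 0))], self.hosted)
        assert calls == []

    def test_unsupported_but_whitelisted_retained(self):
        ex = exon(500, 700, support=(0, 0))
        wl = {(ex.chrom, ex.start, ex.end, ex.strand.value)}
        calls = annotation.call_alu_exons([ex], self.hosted, whitelist=wl)
        assert len(calls) == 1

    def test_single_exon_transcript_dropped(self):
        calls = annotation.call_alu_exons([exon(500, 700, multi=False)], self.hosted)
        assert calls == []

    def test_exon_on_alu_strand_not_called(self):
        # an exon on the element's own strand would be sense exonisation
        calls = annotation.call_alu_exons(
            [exon(500, 700, strand=Strand.MINUS)], self.hosted
        )
        assert calls == []


class TestAnnotationStatus:
    def _reference(self):
        return pd.DataFrame([
            {"chrom": "chr1", "start": 400, "end": 550, "strand": "+",
             "is_alternative": 1, "in_canonical": 1},
            {"chrom": "chr1", "start": 450, "end": 560, "strand": "+",
             "is_alternative": 0, "in_canonical": 1},
            {"chrom": "chr1", "start": 460, "end": 570, "strand": "+",
             "is_alternative": 0, "in_canonical": 0},
        ])

    def _call(self, start, end):
        hosted = annotation.antisense_alus([alu()], [gene()])
        return annotation.call_alu_exons([exon(start, end)], hosted)

    def test_absent_from_reference_is_cryptic(self):
        calls = annotation.classify_annotation_status(self._call(410, 540), self._reference())
        assert calls[0].annotation_status is AnnotationStatus.CRYPTIC

    def test_flagged_alternative(self):
        calls = annotation.classify_annotation_status(self._call(400, 550), self._reference())
        assert calls[0].annotation_status is AnnotationStatus.ALTERNATIVE

    def test_annotated_noncanonical_is_alternative(self):
        calls = annotation.classify_annotation_status(self._call(460, 570), self._reference())
        assert calls[0].annotation_status is AnnotationStatus.ALTERNATIVE

    def test_unflagged_canonical_is_constitutive(self):
        calls = annotation.classify_annotation_status(self._call(450, 560), self._reference())
        assert calls[0].annotation_status is AnnotationStatus.CONSTITUTIVE


def brute_force_merge(exons):
    """Best achievable: every surviving exon is the longest in its overlap set."""
    kept = []
    for candidate in sorted(exons, key=lambda x: (-(x.end - x.start), x.start)):
        if not any(
            k.chrom == candidate.chrom and overlaps(candidate.start, candidate.end, k.start, k.end)
            for k in kept
        ):
            kept.append(candidate)
    return sorted(kept, key=lambda x: (x.chrom, x.start))


class TestMergeNonoverlapping:
    def test_larger_exon_survives(self):
        big, small = exon(100, 220), exon(150, 240)
        assert annotation.merge_nonoverlapping([small, big]) == [big]

    def test_disjoint_exons_both_retained(self):
        a, b = exon(100, 200), exon(300, 400)
        assert annotation.merge_nonoverlapping([a, b]) == [a, b]

    def test_three_way_overlap_keeps_leftmost_of_longest(self):
        exons = [exon(100, 180), exon(120, 220), exon(140, 240)]
        for perm in itertools.permutations(exons):
            merged = annotation.merge_nonoverlapping(list(perm))
            assert len(merged) == 1
            assert (merged[0].start, merged[0].end) == (120, 220)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(
        st.tuples(st.integers(0, 300), st.integers(1, 80)), min_size=0, max_size=12,
    ))
    def test_survivors_form_an_antichain(self, intervals):
        exons = [exon(s, s + l) for s, l in intervals]
        merged = annotation.merge_nonoverlapping(exons)
        assert len(merged) <= len(exons)
        for a, b in itertools.combinations(merged, 2):
            assert not overlaps(a.start, a.end, b.start, b.end)
        expect = brute_force_merge(exons)
        assert [(m.start, m.end) for m in merged] == [(e.start, e.end) for e in expect]


class TestDivergenceGroups:
    @pytest.mark.parametrize("value,group", [
        (23, 1), (99, 1), (100, 2), (121, 2), (122, 3),
        (146, 3), (147, 4), (168, 4), (169, 5), (269, 5),
        (22, None), (300, None),
    ])
    def test_bin_assignment(self, value, group):
        assert annotation.divergence_group(value) == group


class TestAssignGenes:
    def _calls(self, statuses):
        hosted = annotation.antisense_alus([alu()], [gene()])
        calls = []
        for i, status in enumerate(statuses):
            c = annotation.call_alu_exons([exon(400 + i, 560 + i)], hosted)[0]
            c.annotation_status = status
            calls.append(c)
        return calls

    def test_constitutive_takes_priority(self):
        calls = self._calls([
            AnnotationStatus.CONSTITUTIVE, AnnotationStatus.CRYPTIC, AnnotationStatus.CRYPTIC,
        ])
        table, unassigned = annotation.assign_genes(calls, [gene()])
        assert table.iloc[0]["alu_class"] == "constitutive"
        assert unassigned == []

    def test_cryptic_only_gene(self):
        table, _ = annotation.assign_genes(self._calls([AnnotationStatus.CRYPTIC]), [gene()])
        assert table.iloc[0]["alu_class"] == "cryptic"

    def test_low_expression_gene_filtered(self):
        calls = self._calls([AnnotationStatus.CRYPTIC])
        expr = pd.Series({"g1": 0.5})
        table, _ = annotation.assign_genes(calls, [gene()], expression=expr)
        assert len(table) == 0
        table, _ = annotation.assign_genes(calls, [gene()], expression=pd.Series({"g1": 1.5}))
        assert len(table) == 1


class TestDiscoveryOnSyntheticTruth:
    def test_noise_free_recall_and_precision_are_perfect(self, small_dataset):
        ds = small_dataset
        hosted = annotation.antisense_alus(ds.alus, ds.genes)
        calls = annotation.call_alu_exons(ds.predicted_exons, hosted)
        calls = annotation.classify_annotation_status(calls, ds.reference_exons)
        merged = annotation.merge_nonoverlapping(calls)
        found = {(c.exon.chrom, c.exon.start, c.exon.end) for c in merged}
        planted = {(t.chrom, t.exon_start, t.exon_end) for t in ds.exonising_truth()}
        assert found == planted
        truth = ds.truth_by_id()
        for c in merged:
            assert c.annotation_status.value == truth[c.alu.element_id].annotation_status
            assert c.sites_in_alu.value == truth[c.alu.element_id].sites_in_alu
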