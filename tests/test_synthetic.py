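import hashlib

import numpy as np
import pandas as pd
import pytest

from aluforge.scoring import reference_3ss_scorer
from aluforge.splice import longest_u_tract, scan_3ss, scan_5ss
from aluforge.synthetic import (
    ALU_LENGTH,
    SimulationConfig,
    make_count_matrix,
    make_genome,
    make_junction_table,
    make_orthologue_set,
    make_sensitivity_cohort,
)
from aluforge.pipeline import element_transcript_seq
from aluforge.types import Strand


class TestConfigValidation:
    def test_intron_range_too_short_to_host_alu(self):
        cfg = SimulationConfig(intron_length=(100, 200), alu_insertion_rate=0.5)
        with pytest.raises(ValueError, match="too short to host"):
            cfg.validate()

    def test_short_introns_fine_without_insertions(self):
        SimulationConfig(intron_length=(400, 500), alu_insertion_rate=0.0).validate()

    def test_zero_replicates_rejected(self):
        cfg = SimulationConfig(design=(("ctrl", 0), ("siC1", 3)))
        with pytest.raises(ValueError, match="replicate"):
            cfg.validate()

    def test_empty_range_rejected(self):
        cfg = SimulationConfig(exon_length=(200, 100))
        with pytest.raises(ValueError, match="empty range"):
            cfg.validate()


class TestMakeGenome:
    def test_zero_insertion_rate_gives_zero_repeats(self):
        ds = make_genome(SimulationConfig(seed=1, n_genes=6, alu_insertion_rate=0.0))
        assert ds.alus == [] and ds.truth == []

    def test_same_seed_is_byte_identical(self, tmp_path):
        hashes = []
        for run in ("a", "b"):
            ds = make_genome(SimulationConfig(seed=7, n_genes=8))
            paths = ds.write(tmp_path / run)
            digest = hashlib.sha256()
            for key in sorted(paths):
                digest.update(paths[key].read_bytes())
            hashes.append(digest.hexdigest())
        assert hashes[0] == hashes[1]

    def test_twenty_exonising_alus_all_carry_min_u_tract(self, rich_dataset):
        exonising = rich_dataset.exonising_truth()
        assert len(exonising) == 20  # one per gene by construction
        u_min = rich_dataset.config.u_tract_length["exonising"][0]
        for t in exonising:
            assert t.u_tract_length >= u_min

    def test_planted_features_resolve_against_emitted_sequence(self, small_dataset):
        """Coordinates in the truth record index real motifs in the genome."""
        genes = {g.gene_id: g for g in small_dataset.genes}
        alus = {a.element_id: a for a in small_dataset.alus}
        for t in small_dataset.exonising_truth():
            elem = element_transcript_seq(
                small_dataset.genome, alus[t.alu_id], genes[t.gene_id].strand
            )
            assert any(c.boundary == t.motif_3ss_boundary for c in scan_3ss(elem))
            if t.motif_5ss_boundary >= 0:
                assert any(c.boundary == t.motif_5ss_boundary for c in scan_5ss(elem))
            tract = longest_u_tract(elem)
            assert tract.length == t.u_tract_length
            assert tract.start_offset == t.u_tract_offset

    def test_exon_splice_sites_inside_element(self, small_dataset):
        for t in small_dataset.exonising_truth():
            gene_strand = next(
                g.strand for g in small_dataset.genes if g.gene_id == t.gene_id
            )
            acceptor = t.exon_start if gene_strand is Strand.PLUS else t.exon_end - 1
            assert t.start <= acceptor < t.end

    def test_elements_are_antisense_to_host(self, small_dataset):
        genes = {g.gene_id: g for g in small_dataset.genes}
        for t in small_dataset.truth:
            host = genes[t.gene_id]
            if t.orientation == "antisense":
                assert t.strand != host.strand.value
            else:
                assert t.strand == host.strand.value


class TestCountMatrix:
    def test_non_regulated_exon_has_flat_expected_inclusion(self):
        ds = make_sensitivity_cohort(
            200, SimulationConfig(seed=3, dispersion=0.0),
            classes=("non-regulated",), retention_classes=("none",),
        )
        bundle = make_count_matrix(ds)
        alu = bundle.features[bundle.features["class"] == "alu_exon"]["feature_id"]
        by_cond = bundle.counts.loc[alu].T.groupby(bundle.design).mean().mean(axis=1)
        assert by_cond.max() / by_cond.min() == pytest.approx(1.0, rel=0.05)

    def test_delta_ei_ratio_converges_to_planted_value(self):
        """Mean EI ratio over ~1000 replicates approaches the planted 3-fold."""
        cfg = SimulationConfig(
            seed=5, read_depth=200.0,
            design=(("ctrl", 1000), ("siC1", 1000)),
        )
        ds = make_sensitivity_cohort(1, cfg, classes=("shared-target",),
                                     retention_classes=("none",))
        t = ds.truth[0]
        t.delta_ei = {"ctrl": 1.0, "siC1": 3.0}
        t.control_ei = 0.05
        bundle = make_count_matrix(ds)
        fid = f"{t.alu_id}_exon"
        exonic = bundle.features[bundle.features["class"].isin(("exon", "alu_exon"))]
        totals = bundle.counts.loc[exonic["feature_id"]].sum(axis=0)
        ei = bundle.counts.loc[fid] / totals
        ratio = ei[bundle.design == "siC1"].mean() / ei[bundle.design == "ctrl"].mean()
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_zero_depth_gives_all_zero_matrix(self):
        ds = make_sensitivity_cohort(5, SimulationConfig(seed=1, read_depth=0.0))
        bundle = make_count_matrix(ds)
        assert int(bundle.counts.to_numpy().sum()) == 0

    def test_unknown_condition_label_rejected(self):
        cfg = SimulationConfig(design=(("ctrl", 3), ("siMYSTERY", 3)))
        ds = make_sensitivity_cohort(3, SimulationConfig(seed=1))
        ds.config = cfg
        with pytest.raises(ValueError, match="unknown condition"):
            make_count_matrix(ds)


class TestJunctionTable:
    def test_psi_one_never_emits_skipping(self, small_dataset):
        ds = make_genome(SimulationConfig(seed=30, n_genes=10))
        for t in ds.exonising_truth():
            t.tissue_psi = {k: 1.0 for k in t.tissue_psi}
        junc = make_junction_table(ds, depth=200)
        # skipping junctions connect the two flanking exons directly; none of
        # the emitted junctions may span across the Alu-exon
        from aluforge.synthetic import flanking_exons

        for t in ds.exonising_truth():
            up, down = flanking_exons(ds, t)
            mask = (junc["donor_end"] == up[1]) & (junc["acceptor_start"] == down[0])
            assert mask.sum() == 0

    def test_planted_psi_recovered_within_three_binomial_se(self):
        ds = make_genome(SimulationConfig(seed=31, n_genes=10))
        depth = 10_000
        junc = make_junction_table(ds, depth=depth, samples_per_tissue=1)
        from aluforge.synthetic import flanking_exons

        for t in ds.exonising_truth():
            up, down = flanking_exons(ds, t)
            for tissue, planted in t.tissue_psi.items():
                sub = junc[junc["tissue"] == tissue]
                incl_up = sub[(sub["donor_end"] == up[1]) & (sub["acceptor_start"] == t.exon_start)]["count"].sum()
                incl_down = sub[(sub["donor_end"] == t.exon_end) & (sub["acceptor_start"] == down[0])]["count"].sum()
                skip = sub[(sub["donor_end"] == up[1]) & (sub["acceptor_start"] == down[0])]["count"].sum()
                mean_incl = (incl_up + incl_down) / 2
                est = mean_incl / (mean_incl + skip)
                se = np.sqrt(planted * (1 - planted) / depth)
                assert abs(est - planted) <= 3 * max(se, 1e-4)

    def test_jitter_bounded_by_request(self):
        ds = make_genome(SimulationConfig(seed=32, n_genes=8))
        junc = make_junction_table(ds, depth=50, jitter=3)
        from aluforge.synthetic import flanking_exons

        true_ends = set()
        for t in ds.exonising_truth():
            up, down = flanking_exons(ds, t)
            true_ends |= {up[1], t.exon_start, t.exon_end, down[0]}
        for row in junc.itertuples():
            assert min(abs(row.donor_end - e) for e in true_ends) <= 3
            assert min(abs(row.acceptor_start - e) for e in true_ends) <= 3

    def test_invalid_planted_psi_rejected(self):
        ds = make_genome(SimulationConfig(seed=33, n_genes=8))
        ds.exonising_truth()[0].tissue_psi["brain"] = 1.4
        with pytest.raises(ValueError, match="outside"):
            make_junction_table(ds, depth=10)

    def test_excessive_jitter_rejected(self):
        ds = make_genome(SimulationConfig(seed=33, n_genes=8))
        with pytest.raises(ValueError, match="jitter"):
            make_junction_table(ds, depth=10, jitter=9)


class TestOrthologueSet:
    def test_fewer_than_two_species_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="2 species"):
            make_orthologue_set(small_dataset, species=("human",))

    def test_score_patterns_follow_planted_trajectories(self, rich_dataset):
        table, _ = make_orthologue_set(rich_dataset)
        scorer = reference_3ss_scorer()
        truth = rich_dataset.truth_by_id()
        present = table[table["present"] == 1]
        for alu_id, sub in present.groupby("alu_exon_id"):
            sub = sub.sort_values("species_rank")
            distant, human = sub.iloc[0], sub.iloc[-1]
            traj = truth[alu_id].trajectory
            assert human["score"] > 3
            if traj == "emerging":
                assert distant["score"] < 3
            elif traj == "stable":
                assert distant["score"] >= 3
                assert abs(human["score"] - distant["score"]) <= 1
            else:
                assert distant["score"] >= 3
                assert human["score"] - distant["score"] > 1
            for row in sub.itertuples():
                assert scorer.score(row.window) == pytest.approx(row.score, abs=1e-3)

    def test_stable_scores_within_one_unit_of_most_distant(self, rich_dataset):
        table, _ = make_orthologue_set(rich_dataset)
        truth = rich_dataset.truth_by_id()
        present = table[table["present"] == 1]
        for alu_id, sub in present.groupby("alu_exon_id"):
            if truth[alu_id].trajectory != "stable":
                continue
            sub = sub.sort_values("species_rank")
            base = sub.iloc[0]["score"]
            assert (sub["score"] - base).abs().max() <= 1.0

    def test_missing_orthologue_species_get_absent_rows(self, rich_dataset):
        table, _ = make_orthologue_set(rich_dataset)
        truth = rich_dataset.truth_by_id()
        deeper_than_macaque = table[
            (table["species"] == "marmoset")
            & table["alu_exon_id"].map(lambda a: truth[a].deepest_species != "marmoset")
        ]
        if len(deeper_than_macaque):
            assert (deeper_than_macaque["present"] == 0).all()
            assert (deeper_than_macaque["window"] == "").all()
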