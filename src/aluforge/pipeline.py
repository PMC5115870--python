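"""End-to-end pipeline driver on a synthetic (or file-backed) dataset.

Stage order mirrors the analysis flow: discovery -> motif/U-tract scan ->
coding impact -> usage testing -> sensitivity classes -> intron retention ->
tissue PSI -> cross-species trajectories -> summary report.  Every stage
logs its input/output row counts so filter attrition stays auditable, and
the final report is a plain JSON-serialisable dict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import annotation, evolution, introns, orf, psi as psi_mod, report as report_mod
from .scoring import reference_3ss_scorer, reference_5ss_scorer
from .sensitivity import ClassifierConfig, classify_cohort
from .splice import longest_u_tract, scan_3ss, scan_5ss, score_splice_site, strongest_site
from .synthetic import (
    SimulationConfig,
    SyntheticDataset,
    flanking_exons,
    make_count_matrix,
    make_genome,
    make_junction_table,
    make_orthologue_set,
    stage_rng,
)
from .types import Strand, reverse_complement
from .usage import test_feature_usage

logger = logging.getLogger(__name__)

KNOCKDOWN_CONDITIONS = ("siC1", "siC2", "siUPF1", "siC1_siUPF1")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    psi: psi_mod.PsiConfig = field(default_factory=psi_mod.PsiConfig)
    evo: evolution.EvoConfig = field(default_factory=evolution.EvoConfig)
    junction_depth: int = 2000
    psi_min_total_reads: Optional[int] = None  # override for small cohorts

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "simulation" in raw:
            sim = raw["simulation"]
            for key in ("exons_per_gene", "exon_length", "intron_length",
                        "substitution_rate_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "design" in sim:
                sim["design"] = tuple((c, int(n)) for c, n in sim["design"])
            cfg.simulation = SimulationConfig(**sim)
        if "classifier" in raw:
            cfg.classifier = ClassifierConfig(**raw["classifier"])
        if "psi" in raw:
            cfg.psi = psi_mod.PsiConfig(**raw["psi"])
        if "evo" in raw:
            cfg.evo = evolution.EvoConfig(**raw["evo"])
        for key in ("junction_depth", "psi_min_total_reads"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


def element_transcript_seq(genome: Dict[str, str], alu, host_strand: Strand) -> str:
    """Element sequence as read in the host gene's pre-mRNA."""
    seq = genome[alu.chrom][alu.start:alu.end]
    return reverse_complement(seq) if host_strand is Strand.MINUS else seq


def run_all(config: RunConfig, outdir=None, seed: Optional[int] = None) -> dict:
    """Run every stage on a freshly simulated dataset; return the report.

    With ``outdir`` set, stage outputs (tables, BED/GTF/FASTA files) and the
    JSON report are written under it.
    """
    if seed is not None:
        config.simulation.seed = seed
    sim = config.simulation
    report: dict = {"seed": sim.seed}
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- simulate ------------------------------------------------------
    dataset = make_genome(sim)
    truth = dataset.truth_by_id()
    exonising = dataset.exonising_truth()
    logger.info("simulate: %d genes, %d elements, %d exonising",
                len(dataset.genes), len(dataset.alus), len(exonising))
    if out:
        dataset.write(out / "simulated")

    # ---- discovery -----------------------------------------------------
    hosted = annotation.antisense_alus(dataset.alus, dataset.genes)
    calls = annotation.call_alu_exons(dataset.predicted_exons, hosted)
    calls = annotation.classify_annotation_status(calls, dataset.reference_exons)
    merged = annotation.merge_nonoverlapping(calls)
    found = {(ax.exon.chrom, ax.exon.start, ax.exon.end) for ax in merged}
    planted = {(t.chrom, t.exon_start, t.exon_end) for t in exonising}
    recall = len(found & planted) / len(planted) if planted else 1.0
    precision = len(found & planted) / len(found) if found else 1.0
    status_ok = sum(
        1 for ax in merged
        if truth.get(ax.alu.element_id)
        and ax.annotation_status.value == truth[ax.alu.element_id].annotation_status
    )
    report["discovery"] = {
        "n_antisense_intronic_alus": len(hosted),
        "n_alu_exons": len(merged),
        "recall_vs_truth": recall,
        "precision_vs_truth": precision,
        "annotation_status_accuracy": status_ok / len(merged) if merged else 1.0,
    }
    logger.info("discovery: %d calls, recall %.3f precision %.3f",
                len(merged), recall, precision)
    if out:
        from .io import write_alu_exon_bed

        write_alu_exon_bed(merged, out / "alu_exons.bed")

    # ---- motif scan / U-tracts ----------------------------------------
    genes_by_id = {g.gene_id: g for g in dataset.genes}
    s3, s5 = reference_3ss_scorer(), reference_5ss_scorer()
    scan_rows = []
    motif_hits = u_hits = 0
    for t in dataset.truth:
        if t.orientation != "antisense":
            continue
        host = genes_by_id[t.gene_id]
        elem = element_transcript_seq(dataset.genome, _alu_of(dataset, t.alu_id), host.strand)
        calls3 = [score_splice_site(c, s3) for c in scan_3ss(elem)]
        calls5 = [score_splice_site(c, s5) for c in scan_5ss(elem)]
        best3, best5 = strongest_site(calls3), strongest_site(calls5)
        tract = longest_u_tract(elem)
        if t.exonising:
            if any(c.boundary == t.motif_3ss_boundary for c in calls3):
                motif_hits += 1
            if tract.length == t.u_tract_length:
                u_hits += 1
        scan_rows.append({
            "alu_id": t.alu_id, "exonising": t.exonising,
            "best_3ss": best3.score if best3 else np.nan,
            "best_5ss": best5.score if best5 else np.nan,
            "u_tract": tract.length, "u_floored": tract.floored,
            "milli_div": t.milli_div,
            "div_group": annotation.divergence_group(t.milli_div),
        })
    scan_df = pd.DataFrame(
        scan_rows,
        columns=["alu_id", "exonising", "best_3ss", "best_5ss", "u_tract",
                 "u_floored", "milli_div", "div_group"],
    )
    scan_df["exonising"] = scan_df["exonising"].astype(bool)
    n_exonising = int(scan_df["exonising"].sum())
    exo = scan_df[scan_df["exonising"]]
    sil = scan_df[~scan_df["exonising"]]
    report["scan"] = {
        "n_elements_scanned": len(scan_df),
        "planted_3ss_motif_recovery": motif_hits / n_exonising if n_exonising else 1.0,
        "planted_u_tract_recovery": u_hits / n_exonising if n_exonising else 1.0,
        "median_u_tract_exonising": float(exo["u_tract"].median()) if len(exo) else np.nan,
        "median_u_tract_silent": float(sil["u_tract"].median()) if len(sil) else np.nan,
    }
    if out:
        scan_df.to_csv(out / "element_scan.tsv", sep="\t", index=False)

    # ---- coding impact -------------------------------------------------
    impacts = orf.annotate_coding_impacts(merged, genes_by_id, dataset.genome)
    ptc_rows, ptc_correct, ptc_total = [], 0, 0
    for ax, ann in impacts:
        t = truth.get(ax.alu.element_id)
        if ann is None:
            continue
        ptc_total += 1
        if t and ann.impact == t.ptc_class:
            ptc_correct += 1
        ptc_rows.append({
            "exon_id": ax.exon.exon_id, "impact": ann.impact,
            "ptc_position": ann.ptc_position,
            "distance": ann.distance_to_next_junction,
            "junctions_downstream": ann.downstream_junction_count,
            "nmd_rule": ann.nmd_rule_prediction,
        })
    ptc_df = pd.DataFrame(ptc_rows)
    in_cds = ptc_df["impact"].isin(("PTC_plus", "frameshift", "in_frame")) if len(ptc_df) else pd.Series(dtype=bool)
    report["ptc"] = {
        "n_classified": ptc_total,
        "truth_agreement": ptc_correct / ptc_total if ptc_total else 1.0,
        "fraction_in_cds": float(in_cds.mean()) if ptc_total else np.nan,
        "fraction_ptc_plus": float((ptc_df["impact"] == "PTC_plus").mean()) if ptc_total else np.nan,
    }
    if out:
        ptc_df.to_csv(out / "coding_impact.tsv", sep="\t", index=False)

    # ---- usage testing + sensitivity classes --------------------------
    bundle = make_count_matrix(dataset)
    results = {
        cond: test_feature_usage(bundle, cond, "ctrl")
        for cond in KNOCKDOWN_CONDITIONS
    }
    cohort = classify_cohort(bundle, results, config.classifier)
    class_counts = cohort[cohort["set"] == "significant"]["class"].value_counts().to_dict()
    sig_total = int((cohort["set"] == "significant").sum())
    summary = report_mod.summarize_classes(class_counts, sig_total)
    truth_class = {f"{t.alu_id}_exon": t.sensitivity_class for t in exonising}
    merged_calls = cohort.assign(
        planted=cohort["feature_id"].map(truth_class)
    )
    recovered = (
        (merged_calls["class"] == merged_calls["planted"])
        | ((merged_calls["set"] == "non-regulated") & (merged_calls["planted"] == "non-regulated"))
    )
    report["sensitivity"] = {
        "n_significant": sig_total,
        "n_non_regulated": int((cohort["set"] == "non-regulated").sum()),
        "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
        "class_percentages": {
            r["class"]: int(r["percent"]) for _, r in summary.iterrows()
        },
        "planted_class_recovery": float(recovered.mean()) if len(merged_calls) else np.nan,
    }
    if out:
        cohort.to_csv(out / "sensitivity_calls.tsv", sep="\t", index=False)
        summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)

    # ---- intron retention ---------------------------------------------
    cryptic_coords = [
        (ax.exon.chrom, ax.exon.start, ax.exon.end)
        for ax in merged if ax.annotation_status.value == "cryptic"
    ]
    flanks = introns.build_flanking_introns(merged, genes_by_id, cryptic_coords)
    intron_results = results["siC1_siUPF1"]
    intron_results = intron_results[intron_results["class"] == "intron"]
    linked = introns.link_retention(intron_results)
    truth_ret = {t.alu_id: t.retention for t in exonising}
    linked = linked.assign(planted=linked["alu_exon_id"].map(truth_ret))
    ret_ok = (linked["retention"] == linked["planted"]).mean() if len(linked) else np.nan
    report["retention"] = {
        "n_flanking_introns": len(flanks),
        "n_excluded": sum(1 for iv in flanks if not iv.retained),
        "status_counts": linked["retention"].value_counts().to_dict(),
        "planted_retention_recovery": float(ret_ok),
    }
    if out:
        introns.write_intron_bed(flanks, out / "flanking_introns.bed")
        linked.to_csv(out / "retention_status.tsv", sep="\t", index=False)

    # ---- tissue PSI ----------------------------------------------------
    junc = make_junction_table(dataset, depth=config.junction_depth)
    contexts = []
    for t in exonising:
        up, down = flanking_exons(dataset, t)
        contexts.append(psi_mod.ExonContext(
            exon_id=f"{t.alu_id}_exon", chrom=t.chrom,
            exon=(t.exon_start, t.exon_end), upstream=up, downstream=down,
        ))
    psi_cfg = config.psi
    if config.psi_min_total_reads is not None:
        psi_cfg = psi_mod.PsiConfig(
            grace_window=psi_cfg.grace_window,
            min_total_reads=config.psi_min_total_reads,
            no_skipping_psi=psi_cfg.no_skipping_psi,
            apply_no_skipping_rule=psi_cfg.apply_no_skipping_rule,
        )
    psi_df = psi_mod.tissue_psi_summary(junc, contexts, psi_cfg)
    psi_err = []
    for row in psi_df.itertuples():
        t = truth[row.exon_id.replace("_exon", "")]
        for tissue, planted_psi in t.tissue_psi.items():
            got = getattr(row, f"psi_{tissue}", None)
            if got is not None and got == got:
                psi_err.append(abs(got - planted_psi))
    report["psi"] = {
        "n_exons_covered": len(psi_df),
        "median_max_delta_psi": float(psi_df["max_delta_psi"].median()) if len(psi_df) else np.nan,
        "mean_abs_psi_error": float(np.mean(psi_err)) if psi_err else np.nan,
    }
    if out:
        psi_df.to_csv(out / "tissue_psi.tsv", sep="\t", index=False)

    # ---- evolution -----------------------------------------------------
    ortho_table, ortho_seqs = make_orthologue_set(dataset)
    grouped = evolution.records_from_table(ortho_table, ortho_seqs)
    traj_rows = []
    for alu_id, records in grouped.items():
        call = evolution.classify_trajectory(records, config.evo)
        if call is None:
            continue
        t = truth[alu_id]
        human_rec = records[-1]
        u_len, floored, _ = evolution.cross_species_u_tract(
            human_rec.element_seq, human_rec.D, human_rec.D
        ) if human_rec.element_seq else (np.nan, False, False)
        traj_rows.append({
            "alu_exon_id": alu_id, "trajectory": call.trajectory,
            "lineage": call.lineage, "planted": t.trajectory,
            "human_u_tract": u_len,
        })
    traj_df = pd.DataFrame(traj_rows)
    rng = stage_rng(sim.seed, "bootstrap")
    med_table = evolution.group_median_table(
        {
            traj: traj_df.loc[traj_df["trajectory"] == traj, "human_u_tract"].dropna().tolist()
            for traj in sorted(traj_df["trajectory"].unique())
        } if len(traj_df) else {},
        config.evo, rng,
    )
    report["evolution"] = {
        "n_classified": len(traj_df),
        "trajectory_counts": traj_df["trajectory"].value_counts().to_dict() if len(traj_df) else {},
        "planted_trajectory_recovery": float((traj_df["trajectory"] == traj_df["planted"]).mean()) if len(traj_df) else np.nan,
        "u_tract_median_by_trajectory": {
            r["group"]: (None if pd.isna(r["median"]) else r["median"])
            for _, r in med_table.iterrows()
        },
    }
    if out:
        traj_df.to_csv(out / "trajectories.tsv", sep="\t", index=False)
        med_table.to_csv(out / "u_tract_medians.tsv", sep="\t", index=False)

    if out:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=_json_default))
    return report


def _alu_of(dataset: SyntheticDataset, alu_id: str):
    return next(a for a in dataset.alus if a.element_id == alu_id)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
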