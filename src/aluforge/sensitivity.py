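"""Exon-inclusion (EI) estimation and knockdown-sensitivity classification.

EI is a within-sample proportion: reads on the exon divided by reads on all
exons of the same gene.  The inclusion change of a depletion condition is
dEI = EI(depletion) / EI(control), on condition means.  Classification
compares each single depletion's dEI to the co-depletion dEI (the maximal
achievable inclusion):

* repressor-sensitive (hnRNPC+) iff mean(dEI siC1, dEI siC2) / dEI(co) > 0.4,
  otherwise repressor-refractory;
* decay-sensitive (NMD+) iff dEI(siUPF1) / dEI(co) > 0.1,
  decay-refractory iff that share < 0.05, otherwise unassigned.

All inequalities are strict.  Non-regulated exons are a separate set: expressed
in controls and with adjusted p > 0.1 in every knockdown condition; exons with
adjusted p in (0.01, 0.1] in any condition belong to neither set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Set, Tuple

import numpy as np
import pandas as pd

from .usage import CountsBundle, EXONIC_CLASSES

INF = float("inf")
UNDEFINED = float("nan")

CLASS_NMD_SPECIFIC = "NMD-specific"
CLASS_HNRNPC_SPECIFIC = "hnRNPC-specific"
CLASS_SHARED = "shared-target"
CLASS_NON_REGULATED = "non-regulated"
CLASS_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClassifierConfig:
    hnrnpc_share_threshold: float = 0.4
    nmd_share_threshold: float = 0.1
    nmd_refractory_threshold: float = 0.05
    min_control_reads: float = 5.0
    significant_padj: float = 0.01
    nonregulated_padj: float = 0.1

    def __post_init__(self):
        if not self.nmd_refractory_threshold < self.nmd_share_threshold:
            raise ValueError("refractory threshold must sit below the sensitive one")
        for v in (self.hnrnpc_share_threshold, self.nmd_share_threshold,
                  self.nmd_refractory_threshold):
            if not 0 < v < 1:
                raise ValueError("share thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class SensitivityCall:
    exon_id: str
    hnrnpc: str  # "sensitive" | "refractory"
    nmd: str  # "sensitive" | "refractory" | "unassigned"
    combined: str
    hnrnpc_share: float = UNDEFINED
    nmd_share: float = UNDEFINED


def exon_inclusion(bundle: CountsBundle) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample EI and per-condition means for every exonic feature.

    Samples where the gene's exonic total is zero give NaN and are excluded
    from the condition mean.
    """
    exonic = bundle.features[bundle.features["class"].isin(EXONIC_CLASSES)]
    counts = bundle.counts.loc[exonic["feature_id"]]
    gene_tot = counts.groupby(exonic.set_index("feature_id")["gene_id"]).sum()
    denom = gene_tot.loc[exonic["gene_id"]].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ei = counts.to_numpy(float) / np.where(denom > 0, denom, np.nan)
    ei_df = pd.DataFrame(ei, index=counts.index, columns=counts.columns)
    cond_means = ei_df.T.groupby(bundle.design).mean().T
    return ei_df, cond_means


def delta_ei(depletion_mean: float, control_mean: float) -> float:
    """dEI ratio with sentinels: x/0 -> inf, 0/0 -> NaN (undefined)."""
    if control_mean == 0 or math.isnan(control_mean):
        if depletion_mean > 0:
            return INF
        return UNDEFINED
    if math.isnan(depletion_mean):
        return UNDEFINED
    return depletion_mean / control_mean


def classify_sensitivity(
    dei_sic1: float,
    dei_sic2: float,
    dei_siupf1: float,
    dei_codepletion: float,
    config: ClassifierConfig = ClassifierConfig(),
    exon_id: str = "",
) -> SensitivityCall:
    """Classify one significantly regulated exon from its four dEI values."""
    if (
        math.isnan(dei_codepletion)
        or dei_codepletion == 0
        or math.isinf(dei_codepletion)
    ):
        return SensitivityCall(exon_id, "refractory", "unassigned", CLASS_UNASSIGNED)
    h_share = np.nanmean([dei_sic1, dei_sic2]) / dei_codepletion
    n_share = dei_siupf1 / dei_codepletion
    hnrnpc = "sensitive" if h_share > config.hnrnpc_share_threshold else "refractory"
    if math.isnan(n_share):
        nmd = "unassigned"
    elif n_share > config.nmd_share_threshold:
        nmd = "sensitive"
    elif n_share < config.nmd_refractory_threshold:
        nmd = "refractory"
    else:
        nmd = "unassigned"
    if hnrnpc == "sensitive" and nmd == "sensitive":
        combined = CLASS_SHARED
    elif hnrnpc == "sensitive" and nmd == "refractory":
        combined = CLASS_HNRNPC_SPECIFIC
    elif hnrnpc == "refractory" and nmd == "sensitive":
        combined = CLASS_NMD_SPECIFIC
    else:
        combined = CLASS_UNASSIGNED
    return SensitivityCall(
        exon_id, hnrnpc, nmd, combined,
        hnrnpc_share=float(h_share), nmd_share=float(n_share),
    )


def nonregulated_set(
    bundle: CountsBundle,
    padj_tables: Dict[str, pd.DataFrame],
    config: ClassifierConfig = ClassifierConfig(),
    control: str = "ctrl",
    feature_class: str = "alu_exon",
) -> Set[str]:
    """Exons expressed in controls and untouched by every knockdown.

    Requires a mean of at least ``min_control_reads`` raw reads across
    control samples and adjusted p > ``nonregulated_padj`` in every supplied
    condition table.  Exons with adjusted p in the band between the
    significance and non-regulation thresholds in any condition are neither
    significant nor non-regulated and end up in neither set.
    """
    ctrl_samples = bundle.samples_for(control)
    mean_ctrl = bundle.counts[ctrl_samples].mean(axis=1)
    wanted = bundle.features[bundle.features["class"] == feature_class]["feature_id"]
    out = set()
    for fid in wanted:
        if mean_ctrl[fid] < config.min_control_reads:
            continue
        quiet = True
        for table in padj_tables.values():
            padj = table.set_index("feature_id")["padj"].get(fid, np.nan)
            if not (np.isnan(padj) or padj > config.nonregulated_padj):
                quiet = False
                break
        if quiet:
            out.add(fid)
    return out


def classify_cohort(
    bundle: CountsBundle,
    usage_results: Dict[str, pd.DataFrame],
    config: ClassifierConfig = ClassifierConfig(),
    control: str = "ctrl",
    feature_class: str = "alu_exon",
) -> pd.DataFrame:
    """End-to-end classification of every Alu-exon feature in a bundle.

    ``usage_results`` maps the four knockdown conditions (siC1, siC2,
    siUPF1, siC1_siUPF1) to usage-test tables.  The significant set combines
    the conditional two-knockdown rule on the repressor siRNAs with a plain
    adjusted-p cut on the decay factor and the co-depletion; significant
    exons are classified from their dEI shares, non-regulated exons are
    reported as such, and everything else is ignored.
    """
    from .usage import conditional_threshold

    _, cond_means = exon_inclusion(bundle)
    sig = conditional_threshold(
        usage_results["siC1"], usage_results["siC2"],
        strict=config.significant_padj, loose=0.05,
    )
    for cond in ("siUPF1", "siC1_siUPF1"):
        t = usage_results[cond].set_index("feature_id")["padj"]
        sig |= set(t.index[t < config.significant_padj])
    nonreg = nonregulated_set(bundle, usage_results, config, control, feature_class)

    rows = []
    wanted = bundle.features[bundle.features["class"] == feature_class]["feature_id"]
    for fid in wanted:
        if fid in sig:
            means = cond_means.loc[fid]
            ctrl = means[control]
            call = classify_sensitivity(
                delta_ei(means["siC1"], ctrl),
                delta_ei(means["siC2"], ctrl),
                delta_ei(means["siUPF1"], ctrl),
                delta_ei(means["siC1_siUPF1"], ctrl),
                config, exon_id=fid,
            )
            rows.append({
                "feature_id": fid, "set": "significant", "class": call.combined,
                "hnrnpc": call.hnrnpc, "nmd": call.nmd,
                "hnrnpc_share": call.hnrnpc_share, "nmd_share": call.nmd_share,
            })
        elif fid in nonreg:
            rows.append({
                "feature_id": fid, "set": "non-regulated",
                "class": CLASS_NON_REGULATED, "hnrnpc": "refractory",
                "nmd": "refractory", "hnrnpc_share": np.nan, "nmd_share": np.nan,
            })
        else:
            rows.append({
                "feature_id": fid, "set": "ignored", "class": "ignored",
                "hnrnpc": "", "nmd": "", "hnrnpc_share": np.nan, "nmd_share": np.nan,
            })
    return pd.DataFrame(
        rows,
        columns=["feature_id", "set", "class", "hnrnpc", "nmd",
                 "hnrnpc_share", "nmd_share"],
    )
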