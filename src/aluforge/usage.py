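"""Per-feature differential-usage testing on replicate-pooled counts.

This is a deliberately simple stand-in for negative-binomial exon-usage
modelling: for each feature a 2x2 association test of (feature counts vs
rest-of-gene exonic counts) x (condition vs control) on replicate-summed
counts — Pearson chi-square, or Fisher's exact test when any expected cell
is below 5.  It is calibrated under Poisson-like sampling; replicate-level
overdispersion beyond binomial expectation is detected by a guard that
emits a warning, and externally computed result tables in the same schema
(feature_id, log2fc, pvalue, padj) are accepted anywhere results are
consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXONIC_CLASSES = ("exon", "alu_exon")


@dataclass
class CountsBundle:
    """Feature table + counts matrix (features x samples) + design.

    ``features`` columns: feature_id, gene_id, class (exon|alu_exon|intron);
    ``design`` maps sample name -> condition label.
    """

    features: pd.DataFrame
    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self):
        if not set(self.counts.columns) <= set(self.design.index):
            raise ValueError("every sample column needs a design entry")
        missing = set(self.counts.index) - set(self.features["feature_id"])
        if missing:
            raise ValueError(f"features without metadata: {sorted(missing)[:5]}")

    def samples_for(self, condition: str) -> list:
        return [s for s in self.counts.columns if self.design[s] == condition]

    def gene_exonic_totals(self, samples) -> pd.DataFrame:
        exonic = self.features[self.features["class"].isin(EXONIC_CLASSES)]
        sub = self.counts.loc[exonic["feature_id"], samples]
        return sub.groupby(exonic.set_index("feature_id")["gene_id"]).sum()


#: prior degrees of freedom for moderating per-feature dispersion factors
DISPERSION_PRIOR_DF = 20.0


def test_feature_usage(
    bundle: CountsBundle, condition: str, control: str
) -> pd.DataFrame:
    """Usage test of every feature in ``condition`` vs ``control``.

    Returns a table (feature_id, gene_id, class, log2fc, pvalue, padj,
    status).  The Pearson 2x2 statistic is divided by a moderated
    quasi-binomial dispersion factor estimated from within-condition
    replicate heterogeneity (shrunk towards the cohort median, floored at
    1), so counts overdispersed relative to the pooled-binomial model do
    not flood the test with false positives; under binomial/Poisson-like
    sampling the factor is ~1 and the test is the plain chi-square.
    Low-count tables (any expected cell < 5) fall back to Fisher's exact
    test.  log2fc is the log2 ratio of feature/gene proportions (0.5
    pseudocount on the feature counts); features in single-feature genes or
    with zero counts on both sides are flagged untestable and excluded from
    the BH correction.
    """
    cond_samples = bundle.samples_for(condition)
    ctrl_samples = bundle.samples_for(control)
    if not cond_samples or not ctrl_samples:
        raise ValueError(f"no samples for {condition!r} or {control!r}")

    feats = bundle.features[["feature_id", "gene_id", "class"]]
    fids = feats["feature_id"].to_numpy()
    exonic = feats["class"].isin(EXONIC_CLASSES).to_numpy()

    def pooled(samples):
        gene = bundle.gene_exonic_totals(samples).sum(axis=1)
        x = bundle.counts.loc[fids, samples].sum(axis=1).to_numpy(float)
        g = gene.reindex(feats["gene_id"]).fillna(0.0).to_numpy(float)
        rest = np.where(exonic, g - x, g)
        return x, g, rest

    x_c, g_c, rest_c = pooled(ctrl_samples)
    x_k, g_k, rest_k = pooled(cond_samples)

    for group in (cond_samples, ctrl_samples):
        if len(group) > 1:
            _replicate_dispersion_guard(bundle, group)
    phi = moderated_dispersion(bundle)

    untestable_single = (rest_c <= 0) & (rest_k <= 0)
    untestable_zero = (x_c + x_k == 0) & ~untestable_single
    testable = ~(untestable_single | untestable_zero)

    # Pearson X^2 for the 2x2 [[x_c, rest_c], [x_k, rest_k]]
    n = x_c + rest_c + x_k + rest_k
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * (x_c * rest_k - x_k * rest_c) ** 2
        den = (x_c + rest_c) * (x_k + rest_k) * (x_c + x_k) * (rest_c + rest_k)
        x2 = np.where(den > 0, num / den, np.nan)
        pvalue = stats.chi2.sf(x2 / phi, df=1)
        # minimal expected cell of the 2x2
        min_margin_row = np.minimum(x_c + rest_c, x_k + rest_k)
        min_margin_col = np.minimum(x_c + x_k, rest_c + rest_k)
        min_expected = np.where(n > 0, min_margin_row * min_margin_col / n, 0.0)

    exact = testable & (min_expected < 5)
    for i in np.nonzero(exact)[0]:
        _, pvalue[i] = stats.fisher_exact(
            [[x_c[i], rest_c[i]], [x_k[i], rest_k[i]]]
        )
    pvalue[~testable] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2(
            ((x_k + 0.5) / np.maximum(g_k, 1.0)) / ((x_c + 0.5) / np.maximum(g_c, 1.0))
        )
    status = np.where(
        untestable_single, "untestable_single_feature",
        np.where(untestable_zero, "untestable_zero", "ok"),
    )
    result = feats.copy()
    result["log2fc"] = log2fc
    result["pvalue"] = pvalue
    result["status"] = status
    result["padj"] = np.nan
    tested = result["status"] == "ok"
    if tested.any():
        result.loc[tested, "padj"] = multipletests(
            result.loc[tested, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    return result.reset_index(drop=True)


def moderated_dispersion(bundle: CountsBundle) -> np.ndarray:
    """Per-feature quasi-binomial dispersion factors, moderated and floored.

    For every feature, within-condition replicate heterogeneity of the
    feature-vs-rest-of-gene proportion is summed over all conditions as a
    Pearson statistic; its ratio to the pooled degrees of freedom estimates
    the dispersion factor.  Estimates are shrunk towards the cohort median
    with ``DISPERSION_PRIOR_DF`` prior degrees of freedom and floored at 1.
    """
    feats = bundle.features[["feature_id", "gene_id", "class"]]
    fids = feats["feature_id"].to_numpy()
    exonic = feats["class"].isin(EXONIC_CLASSES).to_numpy()
    stat = np.zeros(len(fids))
    df = np.zeros(len(fids))
    for cond in bundle.design.unique():
        samples = bundle.samples_for(cond)
        if len(samples) < 2:
            continue
        x = bundle.counts.loc[fids, samples].to_numpy(float)
        g = bundle.gene_exonic_totals(samples).reindex(feats["gene_id"]).fillna(0.0).to_numpy(float)
        rest = np.where(exonic[:, None], g - x, g)
        ntot = x + rest
        ok = (ntot > 0).all(axis=1)
        xs, ns = x.sum(axis=1), ntot.sum(axis=1)
        ok &= (xs > 0) & (xs < ns)
        p_hat = np.where(ok, xs / np.where(ns > 0, ns, 1.0), np.nan)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = ((x - ntot * p_hat) ** 2) / (ntot * p_hat * (1 - p_hat))
        contrib = np.where(ok[:, None], contrib, 0.0)
        stat += np.nansum(contrib, axis=1)
        df += np.where(ok, len(samples) - 1, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(df > 0, stat / np.maximum(df, 1), 1.0)
    prior = float(np.median(raw[df > 0])) if (df > 0).any() else 1.0
    moderated = (DISPERSION_PRIOR_DF * prior + df * raw) / (DISPERSION_PRIOR_DF + df)
    return np.maximum(moderated, 1.0)


def _replicate_dispersion_guard(bundle: CountsBundle, samples, alpha: float = 1e-4) -> None:
    """Warn when replicate proportions disagree beyond binomial expectation.

    For each feature, the per-replicate feature vs gene-total proportions
    within each condition are tested for homogeneity (chi-square); a large
    fraction of low p-values indicates count overdispersion that the pooled
    2x2 test does not model.
    """
    exonic = bundle.features[bundle.features["class"].isin(EXONIC_CLASSES)]
    gene_tot = bundle.gene_exonic_totals(samples)
    x = bundle.counts.loc[exonic["feature_id"], samples].to_numpy(float)
    n = gene_tot.loc[exonic["gene_id"], samples].to_numpy(float)
    ok = (n > 0).all(axis=1) & (x.sum(axis=1) > 0) & (x.sum(axis=1) < n.sum(axis=1))
    x, n = x[ok], n[ok]
    tested = int(ok.sum())
    if not tested:
        return
    p_hat = x.sum(axis=1, keepdims=True) / n.sum(axis=1, keepdims=True)
    expected = n * p_hat
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.nansum((x - expected) ** 2 / (expected * (1 - p_hat)), axis=1)
    p = stats.chi2.sf(stat, df=len(samples) - 1)
    flagged = int((p < alpha).sum())
    if flagged / tested > 0.10:
        warnings.warn(
            f"replicate proportions overdispersed for {flagged}/{tested} features; "
            "the moderated dispersion correction will damp, but not model, this",
            stacklevel=3,
        )


def conditional_threshold(
    result_a: pd.DataFrame,
    result_b: pd.DataFrame,
    strict: float = 0.01,
    loose: float = 0.05,
) -> Set[str]:
    """Features significant under the two-knockdown conditional rule.

    A feature passes when its adjusted p-value is below ``strict`` in at
    least one of the two tables and below ``loose`` in the other.  Features
    missing from either table are excluded.  Symmetric in its arguments.
    """
    a = result_a.set_index("feature_id")["padj"]
    b = result_b.set_index("feature_id")["padj"]
    common = a.index.intersection(b.index)
    dropped = len(a.index.union(b.index)) - len(common)
    if dropped:
        warnings.warn(f"{dropped} features present in only one result table", stacklevel=2)
    a, b = a[common], b[common]
    hit = ((a < strict) & (b < loose)) | ((b < strict) & (a < loose))
    return set(common[hit.fillna(False)])


def coverage_filter(
    bundle: CountsBundle,
    min_rpm: float = 5.0,
    min_junction: int = 1,
    junction_support: Optional[dict] = None,
    condition: str = "ctrl",
    feature_class: str = "alu_exon",
) -> Set[str]:
    """Exons passing the reads-per-million + junction-read coverage filter.

    RPM is computed per designated sample (default: control condition)
    against that sample's total library size and averaged; features also
    need ``min_junction`` junction-spanning reads (from ``junction_support``,
    feature_id -> count; omitted features count 0).
    """
    samples = bundle.samples_for(condition)
    if not samples:
        raise ValueError(f"no samples for condition {condition!r}")
    lib = bundle.counts[samples].sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size in coverage filter")
    rpm = (bundle.counts[samples] / lib * 1e6).mean(axis=1)
    junction_support = junction_support or {}
    keep = set()
    wanted = bundle.features[bundle.features["class"] == feature_class]["feature_id"]
    for fid in wanted:
        if rpm[fid] >= min_rpm and junction_support.get(fid, 0) >= min_junction:
            keep.add(fid)
    return keep
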