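"""Junction-based percent-spliced-in (PSI) across tissues.

PSI of a cassette exon in one sample is the ratio of inclusion junction
reads (averaged over the upstream and downstream inclusion junctions) to
total junction reads (that average plus the skipping junction count).
Junction ends are matched to annotated splice sites within a small grace
window; tissue-level PSI is the mean over the tissue's samples, and exons
failing a total-read coverage filter are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import pandas as pd


@dataclass(frozen=True)
class PsiConfig:
    grace_window: int = 5
    min_total_reads: int = 200
    no_skipping_psi: float = 1.0
    apply_no_skipping_rule: bool = True

    def __post_init__(self):
        if self.grace_window < 0 or self.min_total_reads < 0:
            raise ValueError("grace window and read filter must be >= 0")


@dataclass(frozen=True)
class ExonContext:
    """Genomic coordinates of an exon and its two flanking exons."""

    exon_id: str
    chrom: str
    exon: Tuple[int, int]
    upstream: Tuple[int, int]  # genomic-left flanking exon
    downstream: Tuple[int, int]  # genomic-right flanking exon


def match_junctions(
    junctions: pd.DataFrame,
    ctx: ExonContext,
    config: PsiConfig = PsiConfig(),
) -> Tuple[int, int, int]:
    """(inclusion_up, inclusion_down, skipping) counts for one exon.

    ``junctions`` rows carry donor_end / acceptor_start / count.  A junction
    end matches a splice site when it lies within ``grace_window`` nt of it;
    a junction with both ends matching counts for the category whose two
    sites are jointly nearest (ties cannot arise between the three
    categories of a cassette exon unless the exon is degenerate).
    """
    sites = {
        "inclusion_up": (ctx.upstream[1], ctx.exon[0]),
        "inclusion_down": (ctx.exon[1], ctx.downstream[0]),
        "skipping": (ctx.upstream[1], ctx.downstream[0]),
    }
    counts = {k: 0 for k in sites}
    sub = junctions[junctions["chrom"] == ctx.chrom]
    for row in sub.itertuples():
        best, best_dist = None, None
        for kind, (donor, acceptor) in sites.items():
            d = abs(int(row.donor_end) - donor)
            a = abs(int(row.acceptor_start) - acceptor)
            if d <= config.grace_window and a <= config.grace_window:
                if best is None or d + a < best_dist:
                    best, best_dist = kind, d + a
        if best is not None:
            counts[best] += int(row.count)
    return counts["inclusion_up"], counts["inclusion_down"], counts["skipping"]


def psi(
    inclusion_up: int,
    inclusion_down: int,
    skipping: int,
    config: PsiConfig = PsiConfig(),
) -> float:
    """PSI from the three junction counts; NaN when all three are zero.

    With no observed skipping reads the exon is reported as fully included
    (PSI = 1) unless the rule is disabled, in which case the value is NaN
    (treated as missing) when inclusion is also absent.
    """
    if min(inclusion_up, inclusion_down, skipping) < 0:
        raise ValueError("junction counts must be >= 0")
    mean_incl = (inclusion_up + inclusion_down) / 2.0
    if mean_incl == 0 and skipping == 0:
        return float("nan")
    if skipping == 0 and config.apply_no_skipping_rule:
        return config.no_skipping_psi
    return mean_incl / (mean_incl + skipping)


def tissue_psi_summary(
    junction_table: pd.DataFrame,
    contexts: Iterable[ExonContext],
    config: PsiConfig = PsiConfig(),
) -> pd.DataFrame:
    """Per-exon tissue PSI table with cross-tissue variability summary.

    ``junction_table`` needs columns chrom, donor_end, acceptor_start,
    count, sample, tissue.  Output rows: one per covered exon with
    per-tissue PSI columns, mean skipping count, max/min PSI and
    max_delta_psi (difference between the most- and least-including
    tissues).  The coverage filter sums, across all samples, the average
    inclusion plus skipping junction reads.
    """
    rows = []
    for ctx in contexts:
        per_sample: List[dict] = []
        for (tissue, sample), sub in junction_table.groupby(["tissue", "sample"]):
            up, down, skip = match_junctions(sub, ctx, config)
            per_sample.append({
                "tissue": tissue, "sample": sample,
                "psi": psi(up, down, skip, config),
                "mean_incl": (up + down) / 2.0, "skip": skip,
            })
        if not per_sample:
            continue
        df = pd.DataFrame(per_sample)
        total_reads = (df["mean_incl"] + df["skip"]).sum()
        if total_reads < config.min_total_reads:
            continue
        tissue_psi = df.groupby("tissue")["psi"].mean().dropna()
        if tissue_psi.empty:
            continue
        row = {
            "exon_id": ctx.exon_id,
            "chrom": ctx.chrom, "start": ctx.exon[0], "end": ctx.exon[1],
            "mean_skipping": float(df["skip"].mean()),
            "max_psi": float(tissue_psi.max()),
            "min_psi": float(tissue_psi.min()),
            "max_delta_psi": float(tissue_psi.max() - tissue_psi.min()),
            "n_tissues": int(tissue_psi.size),
        }
        for tissue, value in tissue_psi.items():
            row[f"psi_{tissue}"] = float(value)
        rows.append(row)
    return pd.DataFrame(rows)
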