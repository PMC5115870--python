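"""Class-count summaries and shared report arithmetic."""

from __future__ import annotations

import math
from typing import Dict, Optional

import pandas as pd

from .sensitivity import (
    CLASS_HNRNPC_SPECIFIC,
    CLASS_NMD_SPECIFIC,
    CLASS_SHARED,
    CLASS_UNASSIGNED,
)

REPORT_CLASS_ORDER = (CLASS_NMD_SPECIFIC, CLASS_HNRNPC_SPECIFIC, CLASS_SHARED)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percentage(count: float, total: float) -> int:
    """Integer percentage of ``count`` in ``total`` (half away from zero)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * count / total)


def summarize_classes(
    class_counts: Dict[str, int], significant_total: Optional[int] = None
) -> pd.DataFrame:
    """Counts and integer percentages of the significantly regulated set.

    ``class_counts`` maps combined-class labels to exon counts; the
    percentage denominator is ``significant_total`` (default: the sum of the
    counts).  When the named classes do not account for the whole
    significant set, the remainder is reported explicitly as unassigned.
    """
    counts = {k: int(v) for k, v in class_counts.items() if k != CLASS_UNASSIGNED}
    explicit_unassigned = int(class_counts.get(CLASS_UNASSIGNED, 0))
    accounted = sum(counts.values())
    if significant_total is not None:
        total = int(significant_total)
        remainder = total - accounted
    else:
        total = accounted + explicit_unassigned
        remainder = explicit_unassigned
    if total == 0:
        return pd.DataFrame(columns=["class", "count", "percent"])
    order = [c for c in REPORT_CLASS_ORDER if c in counts]
    order += [c for c in counts if c not in order]
    rows = [
        {"class": cls, "count": counts[cls], "percent": percentage(counts[cls], total)}
        for cls in order
    ]
    if remainder > 0 or explicit_unassigned:
        rows.append({
            "class": CLASS_UNASSIGNED, "count": remainder,
            "percent": percentage(remainder, total),
        })
    return pd.DataFrame(rows, columns=["class", "count", "percent"])
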