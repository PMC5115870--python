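"""Pluggable splice-site strength scoring.

Splice-site strength is a contract: any pure function mapping a fixed-length
window sequence to a real-valued score can be used.  The bundled reference
scorer is a position log-odds model: for each window position i with observed
base b, it adds log2(f_i(b) / 0.25), where f_i is a per-position frequency
table.  Published maximum-entropy tables can be loaded from TSV files with
:func:`load_frequency_table`; score thresholds used downstream (presence and
change thresholds of the evolutionary classification) are configuration
values and must be recalibrated whenever the scorer is swapped.

Windows:
  * 5'SS: 9 nt = 3 exonic + 6 intronic bases around the donor boundary.
  * 3'SS: 23 nt = 20 nt upstream (ending with the acceptor AG) + 3 nt
    downstream of the acceptor boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence

import numpy as np

BASES = "ACGT"

FIVE_PRIME_WINDOW = 9
THREE_PRIME_WINDOW = 23

# Position of the acceptor AG inside the 23-nt 3'SS window: the upstream 20 nt
# end with the AG dinucleotide, so window[18:20] == "AG" for a canonical site.
ACCEPTOR_AG_OFFSET = 18


@dataclass(frozen=True)
class ScorerModel:
    """A named, pure window -> score function with a fixed window length."""

    name: str
    window_length: int
    score_fn: Callable[[str], float]

    def score(self, window: str) -> float:
        if len(window) != self.window_length:
            raise ValueError(
                f"{self.name}: window length {len(window)} != {self.window_length}"
            )
        return self.score_fn(window)


def _freq_row(order: str, probs: Sequence[float]) -> Dict[str, float]:
    if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
        raise ValueError("frequencies must sum to 1")
    return dict(zip(order, probs))


# Toy per-position frequency tables.  Each non-anchor position carries one
# base at exactly the background frequency 0.25, so a zero-scoring window can
# be written down for any position subset.  Anchor positions (the invariant
# GT/AG-like dinucleotides of the two Alu-derived motif families) are strongly
# peaked.  These numbers are illustrative, not trained on real sites.
_PYRIMIDINE = _freq_row("TCAG", (0.40, 0.25, 0.20, 0.15))
_EXONIC_G = _freq_row("GACT", (0.40, 0.25, 0.20, 0.15))
_PEAKED = {  # anchor base -> frequency row
    "A": _freq_row("ACGT", (0.94, 0.02, 0.02, 0.02)),
    "C": _freq_row("CAGT", (0.94, 0.02, 0.02, 0.02)),
    "G": _freq_row("GACT", (0.94, 0.02, 0.02, 0.02)),
    "T": _freq_row("TACG", (0.94, 0.02, 0.02, 0.02)),
}

# 3'SS: positions 0-16 pyrimidine tract, 17 weakly C-biased, 18-19 the AG,
# 20-22 exonic (G-biased first base of the exon).
THREE_PRIME_TABLE: List[Dict[str, float]] = (
    [_PYRIMIDINE] * 17
    + [_freq_row("CTAG", (0.40, 0.25, 0.20, 0.15))]
    + [_PEAKED["A"], _PEAKED["G"]]
    + [_EXONIC_G] * 3
)

# 5'SS: 3 exonic positions (consensus ...CAG) + 6 intronic (GTAAGT-like;
# within Alu elements the first intronic base is G rather than GT).
FIVE_PRIME_TABLE: List[Dict[str, float]] = [
    _freq_row("CTAG", (0.40, 0.25, 0.20, 0.15)),
    _freq_row("ACGT", (0.40, 0.25, 0.20, 0.15)),
    _PEAKED["G"],
    _PEAKED["G"],
    _freq_row("TCAG", (0.40, 0.25, 0.20, 0.15)),
    _freq_row("ACGT", (0.40, 0.25, 0.20, 0.15)),
    _freq_row("ACGT", (0.40, 0.25, 0.20, 0.15)),
    _freq_row("GACT", (0.40, 0.25, 0.20, 0.15)),
    _freq_row("TCAG", (0.40, 0.25, 0.20, 0.15)),
]


def log_odds_scorer(name: str, table: List[Dict[str, float]]) -> ScorerModel:
    """Build a position log-odds scorer from a per-position frequency table.

    Windows containing ``N`` (or any base absent from the table) score as
    missing (NaN); downstream consumers treat NaN scores as absent sites.
    """

    def score_fn(window: str) -> float:
        total = 0.0
        for pos, base in enumerate(window.upper()):
            freq = table[pos].get(base)
            if freq is None:
                return float("nan")
            total += math.log2(freq / 0.25)
        return total

    return ScorerModel(name=name, window_length=len(table), score_fn=score_fn)


def reference_3ss_scorer() -> ScorerModel:
    return log_odds_scorer("ref-3ss-logodds", THREE_PRIME_TABLE)


def reference_5ss_scorer() -> ScorerModel:
    return log_odds_scorer("ref-5ss-logodds", FIVE_PRIME_TABLE)


def max_score(table: List[Dict[str, float]]) -> float:
    """Best achievable score = sum of per-position maxima."""
    return sum(max(math.log2(f / 0.25) for f in row.values()) for row in table)


def consensus_window(table: List[Dict[str, float]]) -> str:
    """Per-position most frequent base (ties broken by table order)."""
    return "".join(max(row, key=row.get) for row in table)


def load_frequency_table(path) -> List[Dict[str, float]]:
    """Load a per-position frequency table from TSV (columns: pos, A, C, G, T)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = {"pos", "A", "C", "G", "T"} - set(df.columns)
    if missing:
        raise ValueError(f"frequency table missing columns: {sorted(missing)}")
    df = df.sort_values("pos")
    return [_freq_row("ACGT", tuple(row[list("ACGT")])) for _, row in df.iterrows()]


def write_frequency_table(table: List[Dict[str, float]], path) -> None:
    import pandas as pd

    rows = [
        {"pos": i, **{b: row.get(b, 0.0) for b in BASES}}
        for i, row in enumerate(table)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def window_for_score(
    table: List[Dict[str, float]],
    target: float,
    rng: np.random.Generator,
    keep_positions: Sequence[int] = (),
    tol: float = 0.20,
) -> str:
    """Construct a window whose log-odds score is close to ``target``.

    Positions listed in ``keep_positions`` (e.g. an invariant AG anchor) are
    fixed at their consensus base.  The remaining positions are filled
    greedily — each position takes the base whose log-odds contribution is
    closest to the remaining score budget spread over the positions left —
    and a hill-climb over single-position substitutions then closes the
    residual gap.  Raises if the target is outside the achievable range or
    not reached within ``tol``.
    """
    window = list(consensus_window(table))
    contrib = [math.log2(table[i][b] / 0.25) for i, b in enumerate(window)]
    if target > sum(contrib) + tol:
        raise ValueError(f"target {target} above maximal score {sum(contrib):.2f}")

    free = [int(i) for i in rng.permutation(len(table)) if i not in set(keep_positions)]
    remaining = target - sum(contrib[i] for i in set(keep_positions))
    for rank, pos in enumerate(free):
        want = remaining / (len(free) - rank)
        base = min(table[pos], key=lambda b: abs(math.log2(table[pos][b] / 0.25) - want))
        window[pos] = base
        contrib[pos] = math.log2(table[pos][base] / 0.25)
        remaining -= contrib[pos]
    score = sum(contrib)
    for _ in range(20 * max(1, len(free))):
        if abs(score - target) <= tol:
            return "".join(window)
        best = None  # (abs gap after substitution, pos, base, new contrib)
        for pos in free:
            for base, freq in table[pos].items():
                new_c = math.log2(freq / 0.25)
                gap = abs(score - contrib[pos] + new_c - target)
                if best is None or gap < best[0] - 1e-12:
                    best = (gap, pos, base, new_c)
        if best is None or best[0] >= abs(score - target) - 1e-12:
            break  # no single substitution improves further
        _, pos, base, new_c = best
        score += new_c - contrib[pos]
        contrib[pos] = new_c
        window[pos] = base
    if abs(score - target) > tol:
        raise ValueError(f"could not reach target score {target} (got {score:.2f})")
    return "".join(window)
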