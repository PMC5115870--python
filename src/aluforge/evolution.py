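"""Cross-primate 3' splice-site trajectories and bootstrap summaries.

Alu-exons with a strong human 3'SS (score above a presence threshold) are
classified by the evolutionary trajectory of that site across orthologues
ordered from the most distant species to human:

* *emerging* — the site scores below the presence threshold in the most
  distant species carrying the element;
* *evolving* — the site is present in the most distant species and its
  strength increased towards human by more than the change threshold;
* *stable* — present in the most distant species with a change of at most
  the change threshold (a change of exactly the threshold counts as stable,
  and a most-distant score exactly at the presence threshold as present).

Only the most distant and the human scores enter the rule; intermediate
species are informative for plotting but not for classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .scoring import ACCEPTOR_AG_OFFSET
from .splice import longest_run

DEFAULT_SPECIES_ORDER = ("marmoset", "macaque", "gibbon", "chimp", "human")

LINEAGE_NWM = "NWM-shared"
LINEAGE_OWM = "OWM-only"
LINEAGE_HOMINOIDAE = "hominoidae-only"

_LINEAGE_BY_SPECIES = {
    "marmoset": LINEAGE_NWM,
    "macaque": LINEAGE_OWM,
    "gibbon": LINEAGE_HOMINOIDAE,
    "chimp": LINEAGE_HOMINOIDAE,
}

TRAJ_EMERGING = "emerging"
TRAJ_EVOLVING = "evolving"
TRAJ_STABLE = "stable"


@dataclass(frozen=True)
class EvoConfig:
    presence_threshold: float = 3.0
    change_threshold: float = 1.0
    bootstrap_iterations: int = 2000
    ci_level: float = 0.95

    def __post_init__(self):
        if self.presence_threshold <= 0 or self.change_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class OrthologueRecord:
    alu_exon_id: str
    species: str
    window: Optional[str]  # 23-nt 3'SS window, None when the orthologue is absent
    score: Optional[float]
    D: int  # nt from the antisense-Alu start to the 3'SS
    element_seq: Optional[str] = None

    @property
    def present(self) -> bool:
        return self.window is not None and self.score is not None and not math.isnan(self.score)


@dataclass(frozen=True)
class TrajectoryCall:
    alu_exon_id: str
    deepest_species: str
    lineage: str
    trajectory: str
    distant_score: float
    human_score: float


def records_from_table(table: pd.DataFrame, seqs: Optional[dict] = None) -> Dict[str, List[OrthologueRecord]]:
    """Group an orthologue TSV into per-exon record lists (species order kept)."""
    out: Dict[str, List[OrthologueRecord]] = {}
    for row in table.sort_values(["alu_exon_id", "species_rank"]).itertuples():
        present = bool(row.present)
        rec = OrthologueRecord(
            alu_exon_id=row.alu_exon_id,
            species=row.species,
            window=row.window if present else None,
            score=float(row.score) if present else None,
            D=int(row.D),
            element_seq=(seqs or {}).get((row.alu_exon_id, row.species)),
        )
        out.setdefault(row.alu_exon_id, []).append(rec)
    return out


def deepest_species(
    records: Sequence[OrthologueRecord],
    species_order: Sequence[str] = DEFAULT_SPECIES_ORDER,
) -> Optional[Tuple[str, str]]:
    """(species, lineage class) of the most distant present orthologue.

    Returns None when no non-human orthologue exists.
    """
    rank = {s: i for i, s in enumerate(species_order)}
    present = sorted(
        (r for r in records if r.present and r.species != "human"),
        key=lambda r: rank.get(r.species, len(rank)),
    )
    if not present:
        return None
    sp = present[0].species
    return sp, _LINEAGE_BY_SPECIES.get(sp, LINEAGE_HOMINOIDAE)


def classify_trajectory(
    records: Sequence[OrthologueRecord],
    config: EvoConfig = EvoConfig(),
    species_order: Sequence[str] = DEFAULT_SPECIES_ORDER,
) -> Optional[TrajectoryCall]:
    """Trajectory call for one exon; None when the gates exclude it.

    Gates: the human score must exceed the presence threshold and at least
    one non-human orthologue must exist.
    """
    human = next((r for r in records if r.species == "human" and r.present), None)
    if human is None or human.score <= config.presence_threshold:
        return None
    deepest = deepest_species(records, species_order)
    if deepest is None:
        return None
    sp, lineage = deepest
    distant = next(r for r in records if r.species == sp)
    if distant.score < config.presence_threshold:
        traj = TRAJ_EMERGING
    elif human.score - distant.score > config.change_threshold:
        traj = TRAJ_EVOLVING
    else:
        traj = TRAJ_STABLE
    return TrajectoryCall(
        alu_exon_id=records[0].alu_exon_id,
        deepest_species=sp, lineage=lineage, trajectory=traj,
        distant_score=float(distant.score), human_score=float(human.score),
    )


def validate_ag_anchor(window: str) -> bool:
    """The 23-nt window must carry the acceptor AG at its anchored offset."""
    return (
        len(window) == 23
        and window[ACCEPTOR_AG_OFFSET:ACCEPTOR_AG_OFFSET + 2].upper() == "AG"
    )


def cross_species_u_tract(
    element_seq: str,
    three_ss_pos: int,
    D: int,
    min_run: int = 4,
    floor: int = 3,
) -> Tuple[int, bool, bool]:
    """(length, floored, truncated) of the longest U-run near a 3'SS.

    The search window spans D+20 nt upstream to 200-D nt downstream of the
    3'SS (positions in the element sequence, transcript orientation), which
    keeps the region broad enough to contain the element-derived U-tract
    even when the element annotation is incomplete.  Windows extending past
    the available sequence are truncated and flagged.
    """
    lo = three_ss_pos - (D + 20)
    hi = three_ss_pos + (200 - D)
    truncated = lo < 0 or hi > len(element_seq)
    lo, hi = max(0, lo), min(len(element_seq), hi)
    length, _ = longest_run(element_seq[lo:hi])
    if length >= min_run:
        return length, False, truncated
    return floor, True, truncated


def bootstrap_median_ci(
    values: Sequence[float],
    config: EvoConfig = EvoConfig(),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float, float]:
    """Median with a basic (non-studentised pivotal) bootstrap CI.

    The interval is [2m - Q(1-a/2), 2m - Q(a/2)] over the bootstrap-replicate
    medians, with m the sample median.  Needs n >= 2.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap CI needs at least 2 values")
    rng = rng or np.random.default_rng()
    m = float(np.median(values))
    idx = rng.integers(0, values.size, size=(config.bootstrap_iterations, values.size))
    meds = np.median(values[idx], axis=1)
    alpha = 1.0 - config.ci_level
    lo = 2 * m - float(np.quantile(meds, 1 - alpha / 2))
    hi = 2 * m - float(np.quantile(meds, alpha / 2))
    return m, lo, hi


def group_median_table(
    values_by_group: Dict[str, Sequence[float]],
    config: EvoConfig = EvoConfig(),
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Median + bootstrap CI per group (e.g. per species or trajectory)."""
    rows = []
    for group, values in values_by_group.items():
        if len(values) < 2:
            rows.append({"group": group, "n": len(values), "median": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        m, lo, hi = bootstrap_median_ci(values, config, rng)
        rows.append({"group": group, "n": len(values), "median": m, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows, columns=["group", "n", "median", "ci_lo", "ci_hi"])
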