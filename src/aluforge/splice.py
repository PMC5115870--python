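"""Splice-motif scanning and U-tract measurement on Alu element sequences.

All functions take element sequences **in host-gene transcript orientation**,
i.e. the sequence as read in the pre-mRNA.  For an antisense Alu this means
the poly-A-derived element terminus appears at the *start* of the sequence as
a uridine (T) tract.

Two Alu-derived splice-motif families are scanned:

* 5'SS: ``ACAGG`` occurrences, anchored as ``ACAG|G`` (boundary after the
  CAG), scored on a 9-nt window of 3 exonic + 6 intronic bases.
* 3'SS: ``TGAG|AnGG`` (proximal AG) and ``GAGAnAG|`` (distal AG), where n is
  any base and ``|`` marks the acceptor boundary, scored on a 23-nt window of
  20 nt upstream (ending with the AG) + 3 nt downstream.

Overlapping motif occurrences are all reported; deduplication happens only in
:func:`strongest_site`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional

from .scoring import FIVE_PRIME_WINDOW, THREE_PRIME_WINDOW, ScorerModel


@dataclass(frozen=True)
class SpliceSiteCall:
    kind: str  # "5'SS" | "3'SS"
    boundary: int  # offset of the first base AFTER the exon|intron junction
    window: str
    variant: Optional[str] = None  # for 3'SS: "proximal" | "distal"
    score: Optional[float] = None


@dataclass(frozen=True)
class UTract:
    length: int
    start_offset: int  # position of the run within the searched window; -1 if none
    floored: bool


_RE_5SS = re.compile(r"(?=ACAGG)")
_RE_3SS_PROX = re.compile(r"(?=TGAGA[ACGT]GG)")
_RE_3SS_DIST = re.compile(r"(?=GAGA[ACGT]AG)")


def scan_5ss(seq: str) -> List[SpliceSiteCall]:
    """All ACAGG-derived 5' splice-site candidates, left to right.

    The boundary sits after the ACAG; candidates whose 9-nt scoring window
    (3 exonic + 6 intronic bases) would run off the sequence are dropped.
    """
    seq = seq.upper()
    calls = []
    for m in _RE_5SS.finditer(seq):
        boundary = m.start() + 4
        lo, hi = boundary - 3, boundary + 6
        if lo < 0 or hi > len(seq):
            continue
        calls.append(SpliceSiteCall(kind="5'SS", boundary=boundary, window=seq[lo:hi]))
    return calls


def scan_3ss(seq: str) -> List[SpliceSiteCall]:
    """All 3' splice-site candidates from the two Alu acceptor motifs.

    ``TGAGAnGG`` yields a *proximal* call with the boundary after the AG of
    TGAG (position 4 of the match); ``GAGAnAG`` yields a *distal* call with
    the boundary after the terminal AG.  Candidates whose 23-nt window
    (20 nt upstream + 3 nt downstream) is incomplete are dropped.  Calls are
    returned in left-to-right boundary order.
    """
    seq = seq.upper()
    calls = []
    for m in _RE_3SS_PROX.finditer(seq):
        calls.append((m.start() + 4, "proximal"))
    for m in _RE_3SS_DIST.finditer(seq):
        calls.append((m.start() + 7, "distal"))
    out = []
    for boundary, variant in sorted(calls):
        lo, hi = boundary - 20, boundary + 3
        if lo < 0 or hi > len(seq):
            continue
        out.append(
            SpliceSiteCall(
                kind="3'SS", boundary=boundary, window=seq[lo:hi], variant=variant
            )
        )
    return out


def score_splice_site(call: SpliceSiteCall, model: ScorerModel) -> SpliceSiteCall:
    """Attach the model score to a call (N-containing windows score NaN)."""
    expected = FIVE_PRIME_WINDOW if call.kind == "5'SS" else THREE_PRIME_WINDOW
    if len(call.window) != expected:
        raise ValueError(
            f"{call.kind} window length {len(call.window)}, expected {expected}"
        )
    return replace(call, score=model.score(call.window))


def strongest_site(calls: Iterable[SpliceSiteCall]) -> Optional[SpliceSiteCall]:
    """The highest-scoring call; ties break to the leftmost boundary.

    Unscored or NaN-scored calls are ignored; returns None if nothing scored.
    """
    best = None
    for call in calls:
        if call.score is None or math.isnan(call.score):
            continue
        if (
            best is None
            or call.score > best.score
            or (call.score == best.score and call.boundary < best.boundary)
        ):
            best = call
    return best


def longest_run(seq: str, chars: str = "TU") -> tuple:
    """(length, start) of the longest run of ``chars`` in seq; (0, -1) if none.

    Ties break to the leftmost run.
    """
    best_len, best_start = 0, -1
    run_len, run_start = 0, 0
    for i, base in enumerate(seq.upper() + "$"):
        if base in chars:
            if run_len == 0:
                run_start = i
            run_len += 1
        else:
            if run_len > best_len:
                best_len, best_start = run_len, run_start
            run_len = 0
    return best_len, best_start


def longest_u_tract(
    seq: str, window: int = 350, min_run: int = 4, floor: int = 3
) -> UTract:
    """Longest uridine (T) run near the poly-A-derived Alu terminus.

    ``seq`` is the element in transcript orientation, so the terminus — where
    the U-tract of an antisense Alu lies — is at the sequence start; the
    search window is the first ``window`` nt.  Runs straddling the window
    boundary count only their in-window portion.  If no run reaches
    ``min_run``, the element is assigned a floored tract of length ``floor``.
    """
    if not seq:
        raise ValueError("empty sequence")
    length, start = longest_run(seq[:window])
    if length >= min_run:
        return UTract(length=length, start_offset=start, floored=False)
    return UTract(length=floor, start_offset=start, floored=True)
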