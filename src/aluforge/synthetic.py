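"""Synthetic genomes, annotations and count data with planted ground truth.

The generator emulates the structure of the study system — protein-coding
genes whose introns harbour antisense Alu insertions, a subset of which
exonise — so that every downstream stage (discovery, motif scanning, coding
impact, knockdown sensitivity, intron retention, tissue PSI, cross-primate
trajectories) can be tested against a known truth record without any
external data.

Design notes
------------
* The "Alu consensus" is a bundled 300-nt stand-in sequence, scrubbed of the
  two splice-motif families and of uridine runs, so every motif and U-tract
  present in an emitted element was planted deliberately.  Substitutions are
  drawn at the configured per-element rate but applied only to neutral
  filler positions so planted features remain recoverable; the recorded
  per-element divergence (substitutions per 1000 nt) is the bookkeeping value
  downstream analyses consume.
* Sequences are constructed in host-gene transcript orientation and
  reverse-complemented into the genome as needed; an antisense element
  therefore starts with its uridine tract, the reverse-complement read of
  the poly-A tail that drove retrotransposition.
* All randomness flows from ``config.seed`` through per-stage child
  generators, so each emitted table is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as afio
from .scoring import (
    THREE_PRIME_TABLE,
    reference_3ss_scorer,
    window_for_score,
)
from .types import (
    AluElement,
    ExonRecord,
    GeneModel,
    Strand,
    reverse_complement,
)

ALU_LENGTH = 300
STOP_CODONS = ("TAA", "TAG", "TGA")

CONDITIONS = ("ctrl", "no_si", "siC1", "siC2", "siUPF1", "siC1_siUPF1")
CONTROL_CONDITION = "ctrl"

#: depletion-to-control exon-inclusion ratio planted for the co-depletion of
#: the splicing repressor and the decay factor (the maximal inclusion state).
DELTA_EI_CODEPLETION = 20.0

#: planted (repressor share, decay share) of the co-depletion effect per
#: sensitivity class; shares sit well clear of the 0.4 / 0.1 / 0.05
#: classification thresholds (the refractory share is bounded above by the
#: 0.05 cut, so its clearance is necessarily smaller).  ``None`` marks the
#: non-regulated class (no effect in any condition).
CLASS_SHARES = {
    "hnRNPC-specific": (0.70, 0.03),
    "NMD-specific": (0.03, 0.35),
    "shared-target": (0.70, 0.35),
    "non-regulated": None,
}

#: ceiling on any expected exon-inclusion proportion
EI_MAX = 0.9

#: intronic read depth relative to exonic depth, and the fold increase of a
#: retained flank under repressor depletion
INTRON_DEPTH_FRACTION = 0.2
RETENTION_FOLD = 8.0

SENSITIVITY_CLASSES = tuple(CLASS_SHARES)
TRAJECTORY_CLASSES = ("emerging", "evolving", "stable")
RETENTION_CLASSES = ("none", "upstream", "downstream", "both")

DEFAULT_SPECIES = ("marmoset", "macaque", "gibbon", "chimp", "human")
DEFAULT_TISSUES = ("brain", "heart", "liver", "lung", "testis")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for one pipeline stage, derived from the master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 40
    exons_per_gene: Tuple[int, int] = (4, 7)
    exon_length: Tuple[int, int] = (90, 150)
    intron_length: Tuple[int, int] = (700, 1100)
    alu_insertion_rate: float = 0.5
    exonisation_rate: float = 0.6  # fraction of antisense insertions that exonise
    sense_rate: float = 0.1  # fraction of insertions in sense orientation (silent)
    u_tract_length: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"exonising": (8, 16), "silent": (4, 12)}
    )
    substitution_rate_range: Tuple[int, int] = (25, 260)  # per 1000 nt
    read_depth: float = 100.0
    dispersion: float = 0.05
    design: Tuple[Tuple[str, int], ...] = tuple((c, 3) for c in CONDITIONS)
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    species: Tuple[str, ...] = DEFAULT_SPECIES

    def validate(self) -> None:
        for name, (lo, hi) in {
            "exons_per_gene": self.exons_per_gene,
            "exon_length": self.exon_length,
            "intron_length": self.intron_length,
            "substitution_rate_range": self.substitution_rate_range,
        }.items():
            if lo > hi:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")
        for cls, (lo, hi) in self.u_tract_length.items():
            if lo > hi or lo < 4:
                raise ValueError(f"invalid u_tract range for {cls}: ({lo}, {hi})")
        if not 0 <= self.alu_insertion_rate <= 1:
            raise ValueError("alu_insertion_rate must be in [0, 1]")
        if self.alu_insertion_rate > 0 and self.intron_length[0] < ALU_LENGTH + 100:
            raise ValueError(
                f"intron length range {self.intron_length} too short to host a "
                f"{ALU_LENGTH}-nt Alu insertion with 50-nt flanks"
            )
        if any(n < 1 for _, n in self.design):
            raise ValueError("every condition needs >= 1 replicate")
        if self.read_depth < 0 or self.dispersion < 0:
            raise ValueError("read_depth and dispersion must be >= 0")


@dataclass
class PlantedAlu:
    """Ground-truth record for one inserted Alu element."""

    alu_id: str
    gene_id: str
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str  # genomic strand of the element
    orientation: str  # "antisense" | "sense" relative to the host gene
    exonising: bool
    milli_div: int
    u_tract_length: int = 0
    u_tract_offset: int = -1  # within the transcript-oriented element
    exon_start: int = -1  # genomic
    exon_end: int = -1
    sites_in_alu: str = ""  # "both" | "3'SS"
    motif_3ss_boundary: int = -1  # offset within transcript-oriented element
    motif_5ss_boundary: int = -1  # -1 when the donor lies outside the element
    annotation_status: str = ""  # planted cryptic | alternative | constitutive
    sensitivity_class: str = ""
    delta_ei: Dict[str, float] = field(default_factory=dict)
    control_ei: float = 0.0
    ptc_class: str = ""  # PTC_plus | frameshift | in_frame | outside_CDS
    ptc_exon_offset: int = -1  # offset of the stop codon within the exon
    retention: str = ""
    tissue_psi: Dict[str, float] = field(default_factory=dict)
    trajectory: str = ""
    deepest_species: str = ""
    species_scores: Dict[str, float] = field(default_factory=dict)
    species_u_tracts: Dict[str, int] = field(default_factory=dict)
    alu_3ss_distance: int = -1  # D: element start to 3'SS, transcript orientation


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: Dict[str, str]
    genes: List[GeneModel]
    alus: List[AluElement]
    truth: List[PlantedAlu]
    predicted_exons: List[ExonRecord]
    reference_exons: pd.DataFrame

    def truth_by_id(self) -> Dict[str, PlantedAlu]:
        return {t.alu_id: t for t in self.truth}

    def exonising_truth(self) -> List[PlantedAlu]:
        return [t for t in self.truth if t.exonising]

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "genes.gtf",
            "repeats": outdir / "repeats.out",
            "predictions": outdir / "predicted_exons.bed",
            "reference": outdir / "reference_exons.tsv",
            "truth": outdir / "truth.tsv",
        }
        afio.write_fasta(self.genome, paths["genome"])
        afio.write_gtf(self.genes, None, paths["annotation"])
        afio.write_repeatmasker(self.alus, paths["repeats"])
        afio.write_exon_bed(self.predicted_exons, paths["predictions"])
        self.reference_exons.to_csv(paths["reference"], sep="\t", index=False)
        write_truth(self.truth, paths["truth"])
        return paths


def write_truth(truth: List[PlantedAlu], path) -> None:
    rows = []
    for t in truth:
        row = asdict(t)
        for key in ("delta_ei", "tissue_psi", "species_scores", "species_u_tracts"):
            row[key] = json.dumps(row[key])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> List[PlantedAlu]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        kwargs = row.to_dict()
        for key in ("delta_ei", "tissue_psi", "species_scores", "species_u_tracts"):
            kwargs[key] = json.loads(kwargs[key])
        for key in ("annotation_status", "sensitivity_class", "ptc_class",
                    "retention", "trajectory", "deepest_species", "sites_in_alu"):
            if pd.isna(kwargs[key]):
                kwargs[key] = ""
        out.append(PlantedAlu(**kwargs))
    return out


# ---------------------------------------------------------------------------
# Sequence building blocks
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, forbid_t_runs: bool = True) -> list:
    """Random sequence as a list of bases; optionally no TTT run."""
    bases = "ACGT"
    out = []
    for _ in range(length):
        b = bases[rng.integers(4)]
        if forbid_t_runs and b == "T" and out[-2:] == ["T", "T"]:
            b = "ACG"[rng.integers(3)]
        out.append(b)
    return out


_MOTIF_PATTERNS = ("ACAGG", "TGAGA", "GAGA")


def _scrub_motifs(seq: list, rng: np.random.Generator) -> list:
    """Break occurrences of the scanned splice-motif seeds in place."""
    s = "".join(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for pat in _MOTIF_PATTERNS:
            idx = s.find(pat)
            if idx >= 0:
                # replace the middle base with one that breaks the pattern
                mid = idx + len(pat) // 2
                old = seq[mid]
                for b in "ACGT":
                    if b != old and not (b == "T" and "".join(seq[max(0, mid - 2):mid]) == "TT"):
                        seq[mid] = b
                        break
                changed = True
    return seq


def _build_consensus() -> str:
    """The bundled 300-nt Alu stand-in: fixed, motif-free, U-run-free."""
    rng = np.random.default_rng(20090604)
    seq = _scrub_motifs(_random_seq(rng, ALU_LENGTH), rng)
    return "".join(seq)


ALU_CONSENSUS = _build_consensus()


def _stop_free_codons(rng: np.random.Generator, n: int) -> list:
    """n random codons, none a stop, avoiding uridine runs of >= 3."""
    out = []
    tail = ""
    while len(out) < n:
        codon = "".join(_random_seq(rng, 3))
        if codon in STOP_CODONS or "TTT" in (tail + codon):
            continue
        out.append(codon)
        tail = codon[-2:]
    return out


# ---------------------------------------------------------------------------
# Element construction (all in host-gene transcript orientation)
# ---------------------------------------------------------------------------

@dataclass
class _Cassette:
    """A transcript-oriented insertion: element sequence plus optional tail."""

    seq: str  # element (+ tail for exons whose donor lies outside the Alu)
    element_len: int
    u_tract_offset: int
    u_tract_length: int
    exon_rel: Optional[Tuple[int, int]] = None  # exon span within seq
    motif_3ss_boundary: int = -1
    motif_5ss_boundary: int = -1
    sites_in_alu: str = ""


def _apply_substitutions(
    seq: list, protected: set, rate_milli: int, rng: np.random.Generator
) -> list:
    n_subs = int(round(rate_milli / 1000 * len(seq)))
    candidates = [i for i in range(len(seq)) if i not in protected]
    if not candidates or n_subs == 0:
        return seq
    for pos in rng.choice(len(candidates), size=min(n_subs, len(candidates)), replace=False):
        i = candidates[int(pos)]
        alt = [b for b in "ACGT" if b != seq[i]]
        b = alt[rng.integers(3)]
        if b == "T" and (
            "".join(seq[max(0, i - 2):i]) + "T" + "".join(seq[i + 1:i + 3])
        ).count("TTT"):
            b = [x for x in alt if x != "T"][rng.integers(2)]
        seq[i] = b
    return seq


def _silent_element(
    u_len: int, rate_milli: int, rng: np.random.Generator
) -> _Cassette:
    """A non-exonising element: planted U-tract, no splice motifs."""
    pad = 3
    seq = list(ALU_CONSENSUS)
    seq[pad:pad + u_len] = ["T"] * u_len
    # make sure the planted tract is flanked by non-T
    for i in (pad - 1, pad + u_len):
        if 0 <= i < len(seq) and seq[i] == "T":
            seq[i] = "C"
    protected = set(range(pad - 1, pad + u_len + 1))
    seq = _apply_substitutions(seq, protected, rate_milli, rng)
    seq = _scrub_motifs(seq, rng)
    # scrubbing may have touched the tract flanks; re-plant to be safe
    seq[pad:pad + u_len] = ["T"] * u_len
    return _Cassette(
        seq="".join(seq),
        element_len=ALU_LENGTH,
        u_tract_offset=pad,
        u_tract_length=u_len,
    )


def _exonising_element(
    u_len: int,
    exon_len: int,
    frame_codons: list,
    donor_in_alu: bool,
    rng: np.random.Generator,
) -> _Cassette:
    """An exonising element with planted acceptor, donor, U-tract and body.

    ``frame_codons`` is the in-frame codon sequence of the exon body (already
    of the right coding content for the planted class); the body is laid out
    so the exon starts in phase 0 and ends with the ACAG of the donor motif.
    ``donor_in_alu`` False puts the donor ACAGG beyond the element end, so
    only the acceptor lies inside the Alu.
    """
    pad = 3
    gap = 8
    acceptor_motif = "GAGATAG"  # distal acceptor; boundary after the final AG
    head = (
        list("GCA")  # fixed non-U pad so the planted tract cannot extend left
        + ["T"] * u_len
        + ["C"]
        + _scrub_motifs(_random_seq(rng, gap), rng)
        + list(acceptor_motif)
    )
    boundary_3ss = len(head)
    body = list("".join(frame_codons))[: exon_len - 4] + list("ACAG")
    assert len(body) == exon_len
    # the ACAG overwrite can complete an accidental in-frame stop (e.g. TG|A);
    # repair by neutralising the middle base of any stop that was not planted
    for k in range(0, exon_len - 2, 3):
        codon = "".join(body[k:k + 3])
        if codon in STOP_CODONS and "".join(frame_codons)[k:k + 3] != codon:
            body[k + 1] = "C"
    seq = head + body + ["G"]
    boundary_5ss = boundary_3ss + exon_len
    if donor_in_alu:
        filler = _scrub_motifs(_random_seq(rng, max(0, ALU_LENGTH - len(seq))), rng)
        seq = seq + filler
        element_len = len(seq)
        sites = "both"
    else:
        # element ends inside the exon body; donor sits in downstream intron
        element_len = boundary_3ss + exon_len // 2
        sites = "3'SS"
    return _Cassette(
        seq="".join(seq),
        element_len=element_len,
        u_tract_offset=pad,
        u_tract_length=u_len,
        exon_rel=(boundary_3ss, boundary_3ss + exon_len),
        motif_3ss_boundary=boundary_3ss,
        motif_5ss_boundary=boundary_5ss if donor_in_alu else -1,
        sites_in_alu=sites,
    )


def _exon_body_codons(
    ptc_class: str, exon_len: int, rng: np.random.Generator
) -> Tuple[list, int]:
    """Codon content for an exon body of the requested coding-impact class.

    Returns (codons, stop offset within exon or -1).  The body is assembled
    in phase 0; for the frameshift class the caller passes a length with
    ``exon_len % 3 != 0`` and the trailing partial codon never begins a stop
    (the donor ACAG ends the exon).
    """
    n_codons = (exon_len + 2) // 3
    codons = _stop_free_codons(rng, n_codons)
    stop_offset = -1
    if ptc_class == "PTC_plus":
        slot = int(rng.integers(1, max(2, (exon_len - 9) // 3)))
        codons[slot] = "TAA"
        stop_offset = slot * 3
    return codons, stop_offset


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

def _choose(rng: np.random.Generator, items: Sequence, probs: Sequence[float]):
    return items[int(rng.choice(len(items), p=np.asarray(probs) / np.sum(probs)))]


_STATUS_PROBS = (("cryptic", 0.60), ("alternative", 0.25), ("constitutive", 0.15))
_CLASS_PROBS = (
    ("non-regulated", 0.30),
    ("hnRNPC-specific", 0.30),
    ("shared-target", 0.25),
    ("NMD-specific", 0.15),
)
_PTC_PROBS = (
    ("PTC_plus", 0.50),
    ("frameshift", 0.20),
    ("in_frame", 0.15),
    ("outside_CDS", 0.15),
)
_RETENTION_PROBS = (("none", 0.70), ("upstream", 0.10), ("downstream", 0.10), ("both", 0.10))
_TRAJECTORY_PROBS = (("stable", 0.48), ("emerging", 0.27), ("evolving", 0.25))
_DEEPEST_PROBS = (("marmoset", 0.47), ("macaque", 0.39), ("gibbon", 0.07), ("chimp", 0.07))


def make_genome(config: SimulationConfig) -> SyntheticDataset:
    """Generate a genome + annotations + repeat table with planted truth.

    Each gene is laid out in transcript orientation (exon chain with a clean,
    stop-free CDS) and reverse-complemented into the genome for minus-strand
    genes.  At most one exonising Alu is planted per gene, in a randomly
    chosen intron, with the exon starting in coding phase 0 so the planted
    coding-impact class is exact by construction.  Additional silent Alus
    (antisense or sense) are planted in the remaining introns.
    """
    config.validate()
    rng = stage_rng(config.seed, "genome")
    chrom = "chr1"
    genome_parts: List[str] = []
    cursor = 0
    genes: List[GeneModel] = []
    alus: List[AluElement] = []
    truth: List[PlantedAlu] = []
    predicted: List[ExonRecord] = []
    reference_rows: List[dict] = []
    intergenic = 300
    alu_counter = 0

    for g in range(config.n_genes):
        gene_id = f"gene{g:04d}"
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        n_introns = n_exons - 1

        # which introns carry an insertion, and which (at most one) exonises
        inserts: Dict[int, dict] = {}
        for j in range(n_introns):
            if rng.random() < config.alu_insertion_rate:
                inserts[j] = {"kind": "silent-sense" if rng.random() < config.sense_rate else "silent"}
        antisense_slots = [j for j, v in inserts.items() if v["kind"] == "silent"]
        if antisense_slots and rng.random() < config.exonisation_rate:
            j = antisense_slots[int(rng.integers(len(antisense_slots)))]
            inserts[j] = {"kind": "exonising"}

        exonising_slot = next((j for j, v in inserts.items() if v["kind"] == "exonising"), None)

        # ---- transcript-space layout -----------------------------------
        exon_lens = [
            int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            for _ in range(n_exons)
        ]
        utr5 = 30
        ptc_class = ""
        annot_status = ""
        if exonising_slot is not None:
            ptc_class = _choose(rng, *zip(*_PTC_PROBS))
            annot_status = _choose(rng, *zip(*_STATUS_PROBS))
            if annot_status == "constitutive" and ptc_class in ("PTC_plus", "frameshift"):
                ptc_class = "in_frame"  # constitutive exons carry no PTC
        # phase-0 alignment: cumulative exonic length at the host intron must
        # be ≡ utr5 (mod 3) so the inserted exon starts in phase 0
        if exonising_slot is not None and ptc_class != "outside_CDS":
            upstream = sum(exon_lens[: exonising_slot + 1])
            exon_lens[0] += (upstream - utr5) % 3 and (3 - (upstream - utr5) % 3) or 0
            upstream = sum(exon_lens[: exonising_slot + 1])
            assert (upstream - utr5) % 3 == 0

        # CDS span: starts after the 5' UTR; for the outside_CDS class the
        # stop lands before the host intron so the insertion falls in the 3' UTR
        if exonising_slot is not None and ptc_class == "outside_CDS":
            coding_exonic = sum(exon_lens[: exonising_slot + 1]) - utr5 - 20
        else:
            coding_exonic = sum(exon_lens) - utr5 - 30
        coding_exonic -= coding_exonic % 3
        cds_start, cds_end = utr5, utr5 + coding_exonic  # cds_end = one past stop

        # spliced mRNA: UTR + stop-free codons + stop + 3' UTR
        n_codons = coding_exonic // 3 - 1
        mrna = (
            "".join(_random_seq(rng, utr5))
            + "ATG"[:0]  # start codon is simply the first CDS codon below
            + "".join(["ATG"] + _stop_free_codons(rng, n_codons - 1))
            + "TAA"
        )
        mrna += "".join(_random_seq(rng, sum(exon_lens) - len(mrna)))
        assert len(mrna) == sum(exon_lens)

        # cut into exons
        exon_seqs = []
        off = 0
        for L in exon_lens:
            exon_seqs.append(mrna[off:off + L])
            off += L

        # ---- introns with cassettes ------------------------------------
        intron_seqs: List[str] = []
        cassettes: Dict[int, _Cassette] = {}
        cassette_meta: Dict[int, dict] = {}
        for j in range(n_introns):
            ilen = int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            if j not in inserts:
                intron_seqs.append("".join(_random_seq(rng, ilen, forbid_t_runs=False)))
                continue
            kind = inserts[j]["kind"]
            rate = int(rng.integers(*config.substitution_rate_range))
            if kind == "exonising":
                traj = _choose(rng, *zip(*_TRAJECTORY_PROBS))
                u_lo, u_hi = config.u_tract_length["exonising"]
                u_len = int(rng.integers(u_lo, u_hi + 1))
                exon_len = int(rng.integers(60, 121))
                if ptc_class == "frameshift":
                    exon_len += (1 if exon_len % 3 == 0 else 0)
                    if exon_len % 3 == 0:
                        exon_len += 1
                else:
                    exon_len -= exon_len % 3
                codons, stop_off = _exon_body_codons(ptc_class, exon_len, rng)
                donor_in_alu = rng.random() >= 0.2
                cas = _exonising_element(u_len, exon_len, codons, donor_in_alu, rng)
                cassette_meta[j] = {
                    "kind": kind, "rate": rate, "ptc_class": ptc_class,
                    "status": annot_status, "stop_off": stop_off, "trajectory": traj,
                }
            else:
                u_lo, u_hi = config.u_tract_length["silent"]
                u_len = int(rng.integers(u_lo, u_hi + 1))
                cas = _silent_element(u_len, rate, rng)
                cassette_meta[j] = {"kind": kind, "rate": rate}
            cassettes[j] = cas
            left = max(50, (ilen - len(cas.seq)) // 2)
            right = max(50, ilen - len(cas.seq) - left)
            intron_seqs.append(
                "".join(_random_seq(rng, left, forbid_t_runs=False))
                + ("" if kind == "silent-sense" else cas.seq)
                + ("" if kind != "silent-sense" else reverse_complement(cas.seq))
                + "".join(_random_seq(rng, right, forbid_t_runs=False))
            )
            cassette_meta[j]["left_pad"] = left

        # ---- map transcript space to the genome ------------------------
        pre_mrna_parts = []
        texon_spans = []  # (start, end) of each exon within the pre-mRNA
        tpos = 0
        for k in range(n_exons):
            texon_spans.append((tpos, tpos + exon_lens[k]))
            pre_mrna_parts.append(exon_seqs[k])
            tpos += exon_lens[k]
            if k < n_introns:
                pre_mrna_parts.append(intron_seqs[k])
                tpos += len(intron_seqs[k])
        pre_mrna = "".join(pre_mrna_parts)
        glen = len(pre_mrna)
        g0 = cursor

        def to_genomic(span: Tuple[int, int]) -> Tuple[int, int]:
            s, e = span
            if strand is Strand.PLUS:
                return g0 + s, g0 + e
            return g0 + glen - e, g0 + glen - s

        genomic_exons = tuple(sorted(to_genomic(sp) for sp in texon_spans))
        gene = GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand, exons=genomic_exons,
            cds_start=cds_start, cds_end=cds_end,
        )
        genes.append(gene)
        genome_parts.append(pre_mrna if strand is Strand.PLUS else reverse_complement(pre_mrna))
        genome_parts.append("".join(_random_seq(rng, intergenic, forbid_t_runs=False)))
        cursor += glen + intergenic

        # annotated exons are part of the reference (canonical, unflagged)
        for s, e in genomic_exons:
            reference_rows.append(
                {"chrom": chrom, "start": s, "end": e, "strand": strand.value,
                 "is_alternative": 0, "in_canonical": 1}
            )
            predicted.append(
                ExonRecord(chrom=chrom, start=s, end=e, strand=strand,
                           junction_support_left=int(rng.integers(2, 8)),
                           junction_support_right=int(rng.integers(2, 8)))
            )

        # ---- per-cassette bookkeeping ----------------------------------
        for j, cas in cassettes.items():
            meta = cassette_meta[j]
            alu_counter += 1
            alu_id = f"alu{alu_counter:04d}"
            intron_t0 = texon_spans[j][1]  # pre-mRNA offset of intron start
            cas_t0 = intron_t0 + meta["left_pad"]
            elem_span_t = (cas_t0, cas_t0 + cas.element_len)
            g_start, g_end = to_genomic(elem_span_t)
            sense = meta["kind"] == "silent-sense"
            if sense:
                elem_strand = strand
            else:
                elem_strand = strand.opposite
            alu = AluElement(
                chrom=chrom, start=g_start, end=g_end, strand=elem_strand,
                family="AluSynth", milli_div=meta["rate"], element_id=alu_id,
            )
            alus.append(alu)
            planted = PlantedAlu(
                alu_id=alu_id, gene_id=gene_id, chrom=chrom,
                start=g_start, end=g_end, strand=elem_strand.value,
                orientation="sense" if sense else "antisense",
                exonising=meta["kind"] == "exonising",
                milli_div=meta["rate"],
                u_tract_length=cas.u_tract_length,
                u_tract_offset=cas.u_tract_offset,
            )
            if planted.exonising:
                ex_t = (cas_t0 + cas.exon_rel[0], cas_t0 + cas.exon_rel[1])
                ex_g = to_genomic(ex_t)
                planted.exon_start, planted.exon_end = ex_g
                planted.sites_in_alu = cas.sites_in_alu
                planted.motif_3ss_boundary = cas.motif_3ss_boundary
                planted.motif_5ss_boundary = cas.motif_5ss_boundary
                planted.annotation_status = meta["status"]
                planted.ptc_class = meta["ptc_class"]
                planted.ptc_exon_offset = meta["stop_off"]
                planted.sensitivity_class = _choose(rng, *zip(*_CLASS_PROBS))
                planted.control_ei = round(float(rng.uniform(0.02, 0.03)), 6)
                shares = CLASS_SHARES[planted.sensitivity_class]
                if shares is None:
                    planted.delta_ei = {c: 1.0 for c in CONDITIONS}
                else:
                    h, n = shares
                    planted.delta_ei = {
                        "ctrl": 1.0, "no_si": 1.0,
                        "siC1": h * DELTA_EI_CODEPLETION,
                        "siC2": h * DELTA_EI_CODEPLETION,
                        "siUPF1": n * DELTA_EI_CODEPLETION,
                        "siC1_siUPF1": DELTA_EI_CODEPLETION,
                    }
                planted.retention = _choose(rng, *zip(*_RETENTION_PROBS))
                base_psi = float(rng.uniform(0.1, 0.7))
                psi = {t: round(base_psi, 4) for t in config.tissues}
                if rng.random() < 0.3:
                    t = config.tissues[int(rng.integers(len(config.tissues)))]
                    psi[t] = round(min(0.95, base_psi + 0.25), 4)
                planted.tissue_psi = psi
                planted.trajectory = meta["trajectory"]
                planted.deepest_species = _choose(rng, *zip(*_DEEPEST_PROBS))
                planted.alu_3ss_distance = cas.motif_3ss_boundary
                exon_rec = ExonRecord(
                    chrom=chrom, start=ex_g[0], end=ex_g[1], strand=strand,
                    junction_support_left=int(rng.integers(1, 6)),
                    junction_support_right=int(rng.integers(1, 6)),
                    exon_id=f"{alu_id}_exon",
                )
                predicted.append(exon_rec)
                if planted.annotation_status != "cryptic":
                    reference_rows.append(
                        {"chrom": chrom, "start": ex_g[0], "end": ex_g[1],
                         "strand": strand.value,
                         "is_alternative": int(planted.annotation_status == "alternative"),
                         "in_canonical": int(planted.annotation_status == "constitutive")}
                    )
            truth.append(planted)

    genome = {chrom: "".join(genome_parts)}
    reference = pd.DataFrame(
        reference_rows,
        columns=["chrom", "start", "end", "strand", "is_alternative", "in_canonical"],
    )
    return SyntheticDataset(
        config=config, genome=genome, genes=genes, alus=alus, truth=truth,
        predicted_exons=predicted, reference_exons=reference,
    )


def make_sensitivity_cohort(
    n_exons: int,
    config: Optional[SimulationConfig] = None,
    classes: Optional[Sequence[str]] = None,
    retention_classes: Optional[Sequence[str]] = None,
    exons_per_gene: int = 6,
) -> SyntheticDataset:
    """A sequence-free cohort for count-level simulations at scale.

    Builds ``n_exons`` one-Alu-exon genes with planted sensitivity and
    retention classes but no genome sequence — enough structure for
    :func:`make_count_matrix` and the classification stages, cheap enough
    for cohorts of thousands of exons.  Class proportions follow the
    generator defaults unless ``classes`` pins every exon to a fixed cycle.
    """
    config = config or SimulationConfig()
    rng = stage_rng(config.seed, "cohort")
    genes, truth = [], []
    for i in range(n_exons):
        gene_id = f"gene{i:05d}"
        base = i * 50_000
        exons = tuple((base + k * 500, base + k * 500 + 100) for k in range(exons_per_gene))
        genes.append(GeneModel(gene_id=gene_id, chrom="chr1", strand=Strand.PLUS, exons=exons))
        if classes:
            cls = classes[i % len(classes)]
        else:
            cls = _choose(rng, *zip(*_CLASS_PROBS))
        shares = CLASS_SHARES[cls]
        if shares is None:
            dei = {c: 1.0 for c in CONDITIONS}
        else:
            h, n = shares
            dei = {
                "ctrl": 1.0, "no_si": 1.0,
                "siC1": h * DELTA_EI_CODEPLETION, "siC2": h * DELTA_EI_CODEPLETION,
                "siUPF1": n * DELTA_EI_CODEPLETION,
                "siC1_siUPF1": DELTA_EI_CODEPLETION,
            }
        truth.append(PlantedAlu(
            alu_id=f"alu{i:05d}", gene_id=gene_id, chrom="chr1",
            start=exons[1][1] + 100, end=exons[1][1] + 100 + ALU_LENGTH,
            strand="-", orientation="antisense", exonising=True,
            milli_div=int(rng.integers(*config.substitution_rate_range)),
            exon_start=exons[1][1] + 150, exon_end=exons[1][1] + 240,
            sensitivity_class=cls, delta_ei=dei,
            control_ei=round(float(rng.uniform(0.02, 0.03)), 6),
            retention=(
                retention_classes[i % len(retention_classes)]
                if retention_classes else _choose(rng, *zip(*_RETENTION_PROBS))
            ),
        ))
    return SyntheticDataset(
        config=config, genome={}, genes=genes, alus=[], truth=truth,
        predicted_exons=[], reference_exons=pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "is_alternative", "in_canonical"]
        ),
    )


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    """Gamma-Poisson negative binomial draws with Var = mu + a*mu^2."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return rng.poisson(lam)


def make_count_matrix(dataset: SyntheticDataset, config: Optional[SimulationConfig] = None):
    """Per-feature count table across the knockdown design.

    Features are the constitutive exons, the planted Alu-exons and the two
    flanking introns of every Alu-exon.  Counts are negative-binomial; the
    Alu-exon means are set so that the expected exon-inclusion ratio in each
    condition equals the control ratio times the planted inclusion change of
    that condition.
    """
    from .usage import CountsBundle

    config = config or dataset.config
    rng = stage_rng(config.seed, "counts")
    depth, disp = config.read_depth, config.dispersion
    for cond, _ in config.design:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition label: {cond!r}")

    samples, sample_cond = [], {}
    for cond, n in config.design:
        for r in range(1, n + 1):
            name = f"{cond}_r{r}"
            samples.append(name)
            sample_cond[name] = cond

    by_gene: Dict[str, List[PlantedAlu]] = {}
    for t in dataset.exonising_truth():
        by_gene.setdefault(t.gene_id, []).append(t)

    feat_rows, count_rows = [], []
    for gene in dataset.genes:
        n_exons = len(gene.exons)
        base_total = n_exons * depth  # expected reads on constitutive exons
        for k in range(n_exons):
            fid = f"{gene.gene_id}_ex{k}"
            feat_rows.append({"feature_id": fid, "gene_id": gene.gene_id, "class": "exon"})
            count_rows.append((fid, np.concatenate([
                _nb_draw(rng, depth, disp, 1) for _ in samples
            ])))
        for t in by_gene.get(gene.gene_id, []):
            fid = f"{t.alu_id}_exon"
            feat_rows.append({"feature_id": fid, "gene_id": gene.gene_id, "class": "alu_exon"})
            counts = []
            for s in samples:
                cond = sample_cond[s]
                ei = min(EI_MAX, t.control_ei * t.delta_ei.get(cond, 1.0))
                mean = ei / (1.0 - ei) * base_total
                counts.append(_nb_draw(rng, mean, disp, 1))
            count_rows.append((fid, np.concatenate(counts)))
            for side in ("upstream", "downstream"):
                fid = f"{t.alu_id}_intron_{side}"
                feat_rows.append({"feature_id": fid, "gene_id": gene.gene_id, "class": "intron"})
                retained = t.retention in (side, "both")
                counts = []
                for s in samples:
                    cond = sample_cond[s]
                    mult = RETENTION_FOLD if retained and cond in ("siC1", "siC2", "siC1_siUPF1") else 1.0
                    counts.append(_nb_draw(rng, INTRON_DEPTH_FRACTION * depth * mult, disp, 1))
                count_rows.append((fid, np.concatenate(counts)))

    features = pd.DataFrame(feat_rows)
    counts = pd.DataFrame(
        {fid: vals for fid, vals in count_rows}, index=samples
    ).T
    design = pd.Series(sample_cond, name="condition")
    return CountsBundle(features=features, counts=counts, design=design)


# ---------------------------------------------------------------------------
# Junction tables
# ---------------------------------------------------------------------------

def flanking_exons(dataset: SyntheticDataset, planted: PlantedAlu):
    """Genomic (upstream_exon, downstream_exon) intervals around an Alu-exon."""
    gene = next(g for g in dataset.genes if g.gene_id == planted.gene_id)
    for j, (s, e) in enumerate(gene.introns()):
        if s <= planted.exon_start and planted.exon_end <= e:
            return gene.exons[j], gene.exons[j + 1]
    raise ValueError(f"{planted.alu_id}: exon not inside an annotated intron")


def make_junction_table(
    dataset: SyntheticDataset,
    tissues: Optional[Sequence[str]] = None,
    depth: int = 50,
    seed: Optional[int] = None,
    samples_per_tissue: int = 3,
    jitter: int = 0,
) -> pd.DataFrame:
    """Per-sample junction counts (STAR SJ-style) for the planted Alu-exons.

    Inclusion and skipping junction counts are binomial draws at the planted
    per-tissue inclusion level.  With ``jitter`` > 0 both junction ends are
    shifted by up to ``jitter`` nt (at most 5).
    """
    tissues = tuple(tissues or dataset.config.tissues)
    if jitter > 5:
        raise ValueError("jitter must be <= 5 nt")
    rng = stage_rng(seed if seed is not None else dataset.config.seed, "junctions")
    rows = []
    for t in dataset.exonising_truth():
        for tissue, psi in t.tissue_psi.items():
            if not 0.0 <= psi <= 1.0:
                raise ValueError(f"{t.alu_id}: planted PSI {psi} outside [0, 1]")
        up, down = flanking_exons(dataset, t)
        junctions = {
            "inclusion_up": (up[1], t.exon_start),
            "inclusion_down": (t.exon_end, down[0]),
            "skipping": (up[1], down[0]),
        }
        for tissue in tissues:
            psi = t.tissue_psi.get(tissue, 0.0)
            for rep in range(1, samples_per_tissue + 1):
                sample = f"{tissue}_s{rep}"
                counts = {
                    "inclusion_up": rng.binomial(depth, psi),
                    "inclusion_down": rng.binomial(depth, psi),
                    "skipping": rng.binomial(depth, 1.0 - psi),
                }
                for kind, (donor, acceptor) in junctions.items():
                    c = int(counts[kind])
                    if c == 0:
                        continue
                    dj = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                    aj = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                    rows.append({
                        "chrom": t.chrom, "donor_end": donor + dj,
                        "acceptor_start": acceptor + aj,
                        "strand": "+", "count": c,
                        "sample": sample, "tissue": tissue,
                    })
    return pd.DataFrame(
        rows,
        columns=["chrom", "donor_end", "acceptor_start", "strand", "count", "sample", "tissue"],
    )


# ---------------------------------------------------------------------------
# Orthologue sets
# ---------------------------------------------------------------------------

_SCORE_BANDS = {
    # trajectory -> (most-distant score band, human score band)
    "stable": ((3.6, 6.0), None),     # human = distant + U(-0.5, 0.5)
    "evolving": ((3.6, 5.0), None),   # human = distant + U(1.5, 3.0)
    "emerging": ((0.0, 2.4), (3.6, 6.0)),
}

SPECIES_ORDER = {s: i for i, s in enumerate(DEFAULT_SPECIES)}


def make_orthologue_set(
    dataset: SyntheticDataset,
    species: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], str]]:
    """Cross-species 3'SS windows and element sequences per Alu-exon.

    Species are ordered most distant -> human.  For each exon the planted
    trajectory class dictates target scores in the most distant available
    species and in human (intermediates interpolate); 23-nt windows realising
    those scores under the reference scorer are constructed and the achieved
    scores recorded back into the truth.  Species deeper than the planted
    orthologue depth get an absent-window row.
    """
    species = tuple(species or dataset.config.species)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    rng = stage_rng(seed if seed is not None else dataset.config.seed, "orthologues")
    scorer = reference_3ss_scorer()
    rows = []
    seqs: Dict[Tuple[str, str], str] = {}
    for t in dataset.exonising_truth():
        deepest_idx = SPECIES_ORDER.get(t.deepest_species, 0)
        present = [s for s in species if SPECIES_ORDER.get(s, 0) >= deepest_idx]
        distant = present[0]
        band_d, band_h = _SCORE_BANDS[t.trajectory]
        windows = scores = None
        for _attempt in range(50):
            s_d = float(rng.uniform(*band_d))
            if t.trajectory == "stable":
                s_h = s_d + float(rng.uniform(-0.4, 0.4))
            elif t.trajectory == "evolving":
                s_h = s_d + float(rng.uniform(1.6, 3.0))
            else:
                s_h = float(rng.uniform(*band_h))
            windows, scores = _realise_windows(t.trajectory, present, s_d, s_h, rng, scorer)
            if windows is not None:
                break
        if windows is None:
            raise RuntimeError(f"{t.alu_id}: could not realise trajectory windows")
        D = int(rng.integers(25, 61))
        n_present = len(present)
        u_lo = int(rng.integers(6, 10))
        for rank, sp in enumerate(species):
            if sp not in present:
                rows.append({
                    "alu_exon_id": t.alu_id, "species": sp, "species_rank": rank,
                    "present": 0, "window": "", "score": np.nan, "D": D, "u_tract": -1,
                })
                continue
            frac = present.index(sp) / max(1, n_present - 1)
            if t.trajectory == "stable":
                u_len = u_lo
            else:
                u_len = u_lo + int(round(frac * 4))
            elem = _species_element(D, u_len, rng)
            t.species_scores[sp] = round(float(scores[sp]), 4)
            t.species_u_tracts[sp] = u_len
            seqs[(t.alu_id, sp)] = elem
            rows.append({
                "alu_exon_id": t.alu_id, "species": sp, "species_rank": rank,
                "present": 1, "window": windows[sp], "score": round(float(scores[sp]), 4),
                "D": D, "u_tract": u_len,
            })
    columns = ["alu_exon_id", "species", "species_rank", "present", "window",
               "score", "D", "u_tract"]
    return pd.DataFrame(rows, columns=columns), seqs


#: required clearance of the achieved scores from the presence (3) and
#: change (1) thresholds of the trajectory classifier
_SCORE_MARGIN = 0.25


def _realise_windows(trajectory, present, s_d, s_h, rng, scorer):
    """Construct per-species windows and verify the achieved-score margins.

    Returns (windows, scores) keyed by species, or (None, None) when any
    achieved score lands within ``_SCORE_MARGIN`` of a classification
    threshold or on the wrong side of it.
    """
    windows, scores = {}, {}
    n = len(present)
    for i, sp in enumerate(present):
        frac = i / max(1, n - 1)
        target = s_d + frac * (s_h - s_d)
        try:
            w = window_for_score(THREE_PRIME_TABLE, target, rng, keep_positions=(18, 19), tol=0.35)
        except ValueError:
            return None, None
        windows[sp], scores[sp] = w, scorer.score(w)
    a_d, a_h = scores[present[0]], scores[present[-1]]
    if a_h <= 3.0 + _SCORE_MARGIN:
        return None, None
    if trajectory == "emerging":
        ok = a_d <= 3.0 - _SCORE_MARGIN
    elif trajectory == "evolving":
        ok = a_d >= 3.0 + _SCORE_MARGIN and (a_h - a_d) >= 1.0 + _SCORE_MARGIN
    else:
        ok = a_d >= 3.0 + _SCORE_MARGIN and abs(a_h - a_d) <= 1.0 - _SCORE_MARGIN
    return (windows, scores) if ok else (None, None)


def _species_element(D: int, u_len: int, rng: np.random.Generator) -> str:
    """A 300-nt element, 3'SS at offset D, planted U-run near the start."""
    seq = list(ALU_CONSENSUS)
    pad = 3
    seq[pad:pad + u_len] = ["T"] * u_len
    for i in (pad - 1, pad + u_len):
        if 0 <= i < len(seq) and seq[i] == "T":
            seq[i] = "C"
    return "".join(seq)


def write_orthologues(records: pd.DataFrame, seqs, tsv_path, fasta_path) -> None:
    records.to_csv(tsv_path, sep="\t", index=False)
    afio.write_fasta({f"{a}|{s}": seq for (a, s), seq in seqs.items()}, fasta_path)
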