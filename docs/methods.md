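# Methods

This note documents the models and conventions implemented in `aluforge`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the underlying procedure
is genuinely open.

## Coordinates and orientation

Internally every interval is 0-based half-open. GTF I/O is 1-based
inclusive; BED and the internal tables are 0-based half-open; RepeatMasker
`.out` rows are 1-based inclusive and converted on parsing (the
percent-divergence column is converted to substitutions per 1000 nt).

Element sequences are analysed in **host-gene transcript orientation** (the
sequence as read in the pre-mRNA). For an antisense Alu the poly-A-derived
element terminus then appears at the *start* of the sequence as a uridine
(T) run. "The last 350 nt from the element end" is therefore implemented as
the first 350 nt of the transcript-oriented element; users supplying
element-oriented sequences must reverse-complement first. This orientation
choice is deliberate and flagged here because the alternative reading
(transcript-oriented tail) anchors the window at the opposite end.

## Discovery

An exon is an Alu-exon when its acceptor or donor anchor base lies within
`[alu.start, alu.end)` of an element that is fully intronic and antisense to
the exon's host gene. The anchor bases are the first (3'SS) and last (5'SS)
exonic positions in transcript orientation; the published rule names no
anchor base, so this convention is fixed and used consistently. Predictions
must belong to multi-exon transcripts and carry at least one
junction-spanning read, or appear in an externally supplied whitelist (the
mechanism used for exon sets established in another cell line). Annotation
status: absent from the reference exon table → cryptic; present and either
flagged as an alternative event or absent from the canonical transcript set
→ alternative; otherwise constitutive. The canonical-set flag column stands
in for membership of a curated transcript database and is provided by the
user. Overlap merging keeps the larger exon; equal lengths break to the
smaller start coordinate, and an element intronic to qualifying genes on
both strands is treated once per host gene.

## Splice-site model

Scoring is a contract: any pure function window → score. The bundled
reference scorer is a per-position log-odds model, `sum_i log2(f_i(b)/0.25)`
over bundled toy frequency tables (23 positions for the 3'SS — 20 upstream
ending in the acceptor AG, 3 downstream; 9 for the 5'SS — 3 exonic, 6
intronic). The tables are illustrative, not trained; every non-anchor
position carries one base at exactly background frequency so a zero-scoring
window exists. Published maximum-entropy tables can be loaded from TSV
(`scoring.load_frequency_table`); the presence (3) and change (1) thresholds
used by the trajectory classifier are configuration values calibrated to the
bundled scorer's units and **must be recalibrated when the scorer is
swapped**. Windows containing N score as missing; the source procedure does
not state how N was handled.

U-tracts: the longest maximal T-run within the window; runs shorter than
4 nt floor to a reported length of 3 ("no functional tract"); a run
straddling the window edge counts only its in-window portion.

## Coding impact and the 55-nt rule

The reading frame of an inserted exon comes from the exonic distance between
the annotated start codon and the exon start. Codons are anchored at the
start codon; a stop codon counts as inside the exon when its **first base**
is. Exons with no in-frame stop are frame-shift when their in-CDS length is
not a multiple of 3, else in-frame; exons upstream of the start codon or
downstream of the annotated stop are outside the CDS, and exons spanning the
CDS start are classified by the portion inside it (a conservative choice;
the procedure is unstated). PTC-to-junction distance runs from the first
base of the stop codon to the next downstream junction, exclusive; with the
55-nt threshold this yields sensitive-if ≥ 55 nt / refractory-if < 55 nt /
last-exon predictions. Classification is gated, by default, on junction
support at both exon boundaries, which is what makes the frame assignment
trustworthy.

## Usage testing

The differential-usage test is a deliberately simple stand-in for
negative-binomial exon-usage modelling, and external result tables in the
same schema are accepted anywhere its output is consumed. For each feature
it forms the 2×2 table (feature counts vs rest-of-gene exonic counts) ×
(condition vs control) on replicate-summed counts and computes the Pearson
chi-square, falling back to Fisher's exact test when an expected cell is
below 5. Because pooled 2×2 tests assume conditionally binomial proportions,
the statistic is divided by a **moderated quasi-binomial dispersion factor**:
per-feature within-condition replicate heterogeneity (Pearson X²/df summed
over conditions), shrunk towards the cohort median with 20 prior degrees of
freedom and floored at 1. Under Poisson-like sampling the factor is ~1 and
the test reduces to the plain chi-square (type-I error ≈ 0.05, verified by
simulation); under the generator's default overdispersion it is
conservative rather than anticonservative. A guard additionally warns when
more than 10% of features show replicate heterogeneity beyond binomial
expectation. Adjustment is Benjamini–Hochberg across testable features; the
two repressor siRNAs are integrated by conditional thresholding
(padj < 0.01 in at least one, < 0.05 in the other).

## Sensitivity classification

`EI` is a within-sample proportion (library size cancels), averaged across
replicates per condition; `ΔEI` divides a depletion mean by the control
mean, with ∞ and NaN sentinels for zero controls. All classification
thresholds are strict inequalities, matching their published ">"/"<"
phrasing: shares of exactly 0.4 or 0.1 are not sensitive and exactly 0.05 is
unassigned. The significant, non-regulated (≥ 5 mean raw control reads and
padj > 0.1 everywhere) and ignored (padj between 0.01 and 0.1 somewhere)
sets are disjoint by construction, and every significant exon receives
exactly one combined class, with the unassigned remainder always reported
explicitly. The 5-read expression gate uses raw mean counts, configurable to
RPM.

## Intron retention

Flanking introns are the gaps between an Alu-exon and its annotated
neighbours; raw gaps under 60 nt are ignored and the rest shrunk by 25 nt
per side. Introns containing any cryptic exon call (≥ 1 nt overlap — the
partial-overlap rule is unstated and fixed here) are excluded; the
genome-wide variant computes gap introns on the union of annotated plus
own-gene cryptic exons and drops gaps overlapping another gene's annotated
exons. A flank counts as retained when its usage test is significant **and
its usage moved upward**: the direction requirement is needed because
strong exon inclusion inflates the gene denominator and would otherwise
label a denominator-driven drop of the intronic share as retention.

## Tissue PSI

Junction ends match annotated splice sites within a 5-nt grace window,
ambiguity resolved to the jointly nearest pair of sites. PSI is
mean(up, down inclusion) / (that mean + skipping); with zero observed
skipping reads the exon is reported fully included (PSI = 1), a convention
that deliberately inflates PSI where skipping is merely unobserved and can
be disabled. The coverage filter requires 200 reads summed over all samples
(average of the two inclusion junctions plus skipping); a stricter
4000-read variant used for some summaries is the same parameter at a
different value.

## Evolution

Species are ordered most distant → human; the most distant species with a
present orthologue fixes the lineage class (marmoset → NWM-shared, macaque
→ OWM-only, gibbon/chimp → hominoidae-only). Only exons whose human 3'SS
scores above the presence threshold are classified, and only the
most-distant and human scores enter the rule; a strength change of exactly
the change threshold counts as stable and a most-distant score exactly at
the presence threshold as present (both boundary cases are open in the
source phrasing; the conservative side was chosen). Cross-species U-tract
windows span D+20 nt upstream to 200−D nt downstream of the 3'SS, where D is
the element-start-to-3'SS distance — wide enough to catch the tract even
when non-human element annotations are incomplete; windows beyond the
available sequence are truncated and flagged.

Bootstrap confidence intervals of medians use the basic (non-studentised
pivotal) method, `[2m − Q(1−α/2), 2m − Q(α/2)]` over 2000 resample medians,
fully seeded. Quantile statistics are non-smooth, so this interval
undercovers slightly at moderate n (≈ 92% observed at n = 200 against a
95% nominal level, matching scipy's implementation of the same method);
consumers comparing groups should lean on the medians, not on exact
interval coverage.

## Synthetic data generator

The generator defines the study conditions for every test. Genes are built
in transcript space (4–7 exons of 90–150 nt, introns 700–1100 nt, a clean
stop-free CDS) and reverse-complemented into the genome for minus-strand
genes. Antisense insertions occur per intron at rate 0.5; 60% of genes with
an antisense insertion exonise exactly one of them, and 10% of insertions
are sense-orientation silent controls. The "Alu consensus" is a fixed,
bundled 300-nt stand-in scrubbed of both splice-motif families and of T
runs, so every motif and U-tract in an emitted element was planted:
exonising elements carry a distal acceptor (`GAGATAG`), an exon body laid
out in coding phase 0 whose content realises the planted coding-impact
class, a donor `ACAGG` (inside the element for 80% of exons, downstream of
it otherwise), and a U-tract of 8–16 nt; silent elements carry a 4–12-nt
tract and no motifs. Substitutions are drawn per element at 25–260 per
1000 nt but applied only to neutral filler, so the recorded divergence is
bookkeeping and planted features stay exactly recoverable.

Counts are gamma-Poisson (negative binomial) with dispersion 0.05 and a
mean exonic depth of 100 reads per exon per sample, triplicates across six
conditions (two controls, two repressor siRNAs, the decay-factor siRNA and
the co-depletion). Planted effects: control inclusion 2–3%, co-depletion
inclusion change ×20, repressor share 0.70 (sensitive) or 0.03
(refractory), decay share 0.35 or 0.03 — all well clear of the 0.4/0.1/0.05
rules, noting the refractory share is bounded above by 0.05 so its
clearance is intrinsically smaller. Flanking-intron features run at 20% of
exonic depth with an 8-fold increase on retained flanks under repressor
depletion. Junction counts are binomial at the planted per-tissue PSI;
orthologue windows are constructed to hit trajectory-consistent target
scores under the reference scorer (achieved scores are recorded back into
the truth and kept ≥ 0.25 units from both thresholds). All randomness
derives from a single seed through named per-stage child generators, so
identical configurations are byte-identical and sub-tables independently
reproducible.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: read-level artefacts (mapping bias, soft-clips,
duplicates), real Alu subfamily structure and phylogeny, correlated
expression across genes, isoform complexity beyond one flattened transcript
per gene, batch effects, and genuinely weak/borderline regulatory effects —
planted effects are sized to be resolvable at desk scale, so recovery rates
measure the pipeline's correctness, not its power on marginal signals.

## Problem sizes

Default test and acceptance runs use 20–40 simulated genes for sequence-level
stages, 2000-feature cohorts for the statistical recovery and calibration
suites, junction depths of 10⁴ reads for PSI recovery, and 500–1000-case
oracle comparisons; these sizes were chosen to make every planted effect
statistically decisive while keeping any single suite under a minute.

## Known limitations

* The usage test is not a negative-binomial GLM; gene-level differential
  expression is out of scope (external result tables are accepted).
* The bundled splice-site scorer is a toy model; scores are comparable only
  within one scorer, and all score thresholds are scorer-relative.
* Branch-point strength is not modelled.
* Sense-orientation exonisation and non-Alu repeat families are out of
  scope by design.
* PSI is junction-only; isoform-level quantification and partial-retention
  sub-events are not distinguished.
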