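# aluforge

Detection and regulatory classification of **antisense Alu exonisation** from
RNA-seq-derived inputs.

Alu elements are ~300-nt primate retrotransposons; inserted antisense to a
host gene, their poly-A tail reads as a uridine tract (U-tract) in the
pre-mRNA and nearby cryptic splice sites can turn intronic Alu sequence into
an exon. Two surveillance layers keep most of these exons silent: the
RNA-binding protein hnRNPC represses the cryptic 3' splice site through the
U-tract, and nonsense-mediated decay (NMD) degrades many of the transcripts
that do include an Alu-exon, since these usually carry a premature
termination codon (PTC). `aluforge` implements the computational side of
studying this system, for bioinformaticians who have alignments/predictions
in hand and need the downstream analysis:

* **Discovery** — parse RepeatMasker repeat tables and exon predictions, keep
  exons with a splice site inside an intronic antisense Alu and
  junction-read support, classify them as cryptic / alternative /
  constitutive, and collapse overlaps (larger exon wins).
* **Splice elements** — scan element sequences for the Alu-derived motif
  families `ACAG|G` (5'SS) and `TGAG|AnGG` / `GAGAnAG|` (3'SS), score them
  with a pluggable strength model, and measure the longest U-tract in the
  350 nt nearest the poly-A-derived element terminus (runs < 4 nt floor to
  3 nt).
* **Coding impact** — insert an exon into its transcript model, derive the
  reading frame from the annotated start codon, call `PTC+` / frame-shift /
  in-frame / outside-CDS, and evaluate the 55-nt rule: a PTC ≥ 55 nt
  upstream of the next exon-exon junction predicts NMD sensitivity.
* **Usage testing** — a per-feature 2×2 usage test (feature vs rest-of-gene
  counts, condition vs control, quasi-binomial dispersion correction, BH
  adjustment), the two-siRNA conditional threshold (padj < 0.01 in one,
  < 0.05 in the other) and coverage filters.
* **Sensitivity classes** — exon inclusion `EI = exon reads / reads on all
  exons of the gene`, inclusion change `ΔEI = EI(depletion)/EI(control)`,
  and the share rules: hnRNPC-sensitive iff
  `mean(ΔEI siC1, siC2)/ΔEI(co-depletion) > 0.4`; NMD-sensitive iff
  `ΔEI(siUPF1)/ΔEI(co) > 0.1`, NMD-refractory iff that share < 0.05 — giving
  NMD-specific, hnRNPC-specific, shared-target, non-regulated and unassigned
  exons.
* **Intron retention** — trimmed flanking-intron intervals (drop < 60 nt,
  shrink 25 nt per side), genome-wide gap introns, and per-exon retention
  status (upstream / downstream / both / none).
* **Tissue PSI** — junction-based percent-spliced-in with a 5-nt grace
  window, a 200-read coverage filter, and the no-skipping-reads → PSI = 1
  convention; cross-tissue max ΔPSI.
* **Evolution** — cross-primate 3'SS trajectories over
  marmoset < macaque < gibbon < chimp < human: *emerging* (score < 3 in the
  most distant species), *evolving* (present and strengthened towards human
  by > 1), *stable* (present, change ≤ 1); cross-species U-tract windows
  anchored at distance D from the element start; bootstrap
  (non-studentised pivotal) confidence intervals of medians.
* **Synthetic data** — a generator that emits genomes, GTF/BED annotations,
  RepeatMasker-style tables, negative-binomial count matrices, junction
  tables and orthologue sets with a machine-readable planted truth, so the
  whole pipeline is testable without external data.

## Worked example

```python
from aluforge.pipeline import RunConfig, run_all

cfg = RunConfig()
cfg.simulation.n_genes = 40      # simulate a 40-gene cohort
cfg.psi_min_total_reads = 100    # coverage filter scaled to cohort size
report = run_all(cfg, seed=1)
print(report["discovery"], report["sensitivity"]["class_percentages"])
```

prints (seed 1):

```
{'n_antisense_intronic_alus': 83, 'n_alu_exons': 26,
 'recall_vs_truth': 1.0, 'precision_vs_truth': 1.0,
 'annotation_status_accuracy': 1.0}
{'NMD-specific': 21, 'hnRNPC-specific': 71, 'shared-target': 7}
```

Read: of 83 intronic antisense elements, 26 exonise; discovery recovers all
of them and nothing else (recall and precision 1.0 against the planted
truth). Among the 14 exons called significantly regulated by the knockdown
analysis, 71% respond to hnRNPC depletion only, 21% to UPF1 depletion only
and 7% to both; each classified exon matched its planted class. The same
report carries PTC composition, retention status counts, tissue PSI
summaries and trajectory medians; `run_all(cfg, outdir=...)` additionally
writes every stage table (BED/GTF/FASTA/TSV) plus `report.json`.

The same stages are exposed on the command line:

```sh
aluforge simulate --seed 1 --n-genes 40 --out sim/
aluforge discover --genome sim/genome.fa --repeats sim/repeats.out \
    --annotation sim/genes.gtf --predictions sim/predicted_exons.bed \
    --reference sim/reference_exons.tsv --out alu_exons.tsv
aluforge scan --genome sim/genome.fa --repeats sim/repeats.out \
    --annotation sim/genes.gtf --calls-out calls.tsv --utracts-out utracts.tsv
aluforge ptc --genome sim/genome.fa --annotation sim/genes.gtf \
    --alu-exons alu_exons.tsv --out coding_impact.tsv
aluforge run-all --seed 1 --out run/
```

## Documentation

`docs/methods.md` describes the models, parameter choices, the synthetic
generator's assumptions and the package's known limitations.
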