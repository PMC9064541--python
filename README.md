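# rnaedit

Blood A-to-I RNA editing as a diagnostic readout for mood disorders:
a tested, reusable re-implementation of the full analysis chain behind
editing-based biomarker panels — from targeted amplicon reads to a
class-balanced random-forest diagnostic classifier.

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA;
sequencers read inosine as guanosine, so editing at a genomic A appears as
an A→G mismatch. At a reference-A position the **editing percent** is

```
editing % = G / (G + A) × 100
```

over the reads covering it (C/T/N reads are ignored). Beyond per-site
rates, each read phases the editing states of all sites it spans, giving
**edited mRNA isoform** proportions (a read with G at sites B and C is
isoform "BC"). The package is aimed at transcriptomics groups building or
auditing editing-based biomarker panels from targeted deep sequencing, and
covers:

- **quantification** (`rnaedit.quant`): read pre-filters (length ≥ 100 nt,
  mean Phred ≥ 20), a 20,000-read minimum depth rule per sample × target,
  per-position pileup, the editing formula, automatic site detection
  (> 0.1%), per-read isoform phasing (≥ 0.1% proportion threshold), and
  the coverage-weighted Alu editing index
  AEI = ΣG / Σ(A+G) × 100 over Alu positions;
- **discovery filtering** (`rnaedit.discovery`): high-confidence call
  filters (base quality > 25, MAPQ > 20, coverage > 30×, ≥ 2 edited reads,
  editing degree ≥ 10%, removal of 100%-edited positions, group-test
  p < 0.05) and the six stringent biomarker criteria (non-intergenic,
  > 100 bp from known SNPs, detected in ≥ 25% of samples, median/mean
  coverage ≥ 30×, fold change ≤ 0.8 or ≥ 1.20, p < 0.05, AUC > 0.7),
  with full per-criterion provenance;
- **differential statistics** (`rnaedit.differential`): ComBat-style
  empirical-Bayes batch adjustment protecting the diagnosis effect and
  clinical covariates, rank-based inverse-normal transformation,
  data-driven test selection (Student / Welch / Mann-Whitney), fold
  changes, empirical ROC AUC and Benjamini–Hochberg adjustment;
- **Target Editing Index** (`rnaedit.tei`): per gene, the unit-norm linear
  combination w·x of its significant editing biomarkers that maximizes
  empirical ROC AUC on the training samples;
- **MultDS classifier** (`rnaedit.classify`): stratified 70/30 split, then
  an ensemble of balanced random forests — each trained on all
  minority-class training samples plus an equal-size majority draw, with
  mtry tuned by 10-fold cross-validated AUC (defaults ntree = 1000,
  nodesize = 25, 100 models) — probabilities averaged across models,
  evaluated on held-out samples with a DeLong 95% CI and Youden-threshold
  sensitivity/specificity;
- **synthetic data** (`rnaedit.synthetic`): cohorts emulating a
  two-step depression study design (143 controls / 267 depressed; 160
  unipolar / 95 bipolar / 12 uncertain, with age, severity-score,
  treatment and addiction structure), editome site tables with planted
  effects and batch shifts, and amplicon reads (FASTQ + SAM) drawn from a
  known isoform distribution with a per-read truth table.

No clinical data ship with the package; every stage is exercised on
synthetic inputs with known ground truth.

## Worked example

Quantify a simulated amplicon and phase its isoforms:

```python
from rnaedit import quant, synthetic

design = synthetic.default_designs()["GAB2"]          # 3 sites: A, B, C
synthetic.simulate_amplicon_reads(
    design, {"WT": 0.5, "AC": 0.3, "B": 0.2},
    depth=20_000, seed=3, sam_path="gab2.sam",
)
counts = quant.pileup_counts("gab2.sam", design)
print({lab: round(quant.editing_percent(counts[pos]), 2)
       for lab, pos in zip(design.site_labels, design.site_positions)})
props, tally = quant.isoform_proportions("gab2.sam", design)
print(props, tally.eligible)
```

prints

```
{'A': 29.88, 'B': 19.93, 'C': 29.88}
{'AC': 29.88, 'B': 19.93, 'WT': 50.19} 20000
```

i.e. sites A and C are each edited in 29.88% of reads — exactly the
fraction of reads carrying the AC isoform, since no other pattern edits
them — site B in 19.93%, and the isoform proportions recover the planted
50/30/20 mixture to within binomial sampling error at 20,000 reads.

Run the whole pipeline on a small planted-effect cohort from the shell:

```
rnaedit demo --seed 0 --outdir demo_out
```

which simulates a cohort, quantifies, filters, adjusts for batch and
covariates, fits per-gene TEIs on the training split and reports held-out
classifier performance, e.g.
`AUC 0.988 (CI 95% [0.966-1.000]), Se 91.7%, Sp 91.7% ...`
(planted effects are strong by construction; the value states that the
chain recovers them, not that clinical performance would match).

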