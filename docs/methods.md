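# Methods

This note documents the models, procedures and numerical choices behind
`rnaedit`, and what the synthetic-data tests do and do not demonstrate.

## Quantification model

Editing is quantified per reference-A position as G/(G+A)×100 over
retained reads; C, T and N reads are excluded from the denominator, so
sequencing errors to those bases do not bias the rate. A position with no
A- or G-supporting coverage is *missing*, never 0 — reporting 0 would
assert an unedited site without evidence. On minus-strand targets the
same logic applies to the reverse complement, i.e. C/(C+T) on the forward
genomic strand.

Pre-filters follow ultra-deep amplicon practice: reads shorter than
100 nt or with mean Phred below 20 are removed (tallied by first failing
rule), and a sample × target combination needs at least 20,000 retained
reads to enter statistics. The depth boundary is inclusive: exactly
20,000 passes, reading "minimal depth of 20,000" as a minimum that is
itself admissible. Records with indels, secondary/supplementary flags or
unmapped status are expected to be removed by the upstream aligner chain
and are skipped (and not counted toward depth).

Site detection is strict: editing percent must exceed 0.1 (percent
scale). The threshold is interpreted on the percent scale — one edited
read per thousand — consistent with the 0.1% floor applied to isoform
proportions; the alternative reading (fraction 0.1 = 10%) would contradict
that floor and is not used.

### Isoform phasing

An isoform is the set of edited sites carried by one molecule, named by
the concatenated site letters ('A', 'B', 'C', … assigned in ascending
genomic order; "WT" when none). Only reads spanning *all* of a design's
sites are eligible — patterns from partial reads would be ambiguous — and
reads with a non-A/G base at any site are excluded and tallied, mirroring
the site formula. Proportions are percentages of eligible reads; they sum
to 100 before the 0.1% rarity cut. With a single-site design the isoform
table reduces exactly to (editing %, 100 − editing %).

### Alu editing index

AEI is the coverage-weighted aggregate ΣG/Σ(A+G)×100 over A positions in
Alu repeats: a global editing summary dominated by well-covered positions,
deliberately not an average of per-site rates. Zero Alu coverage is
undefined (missing).

## Discovery filtering

The high-confidence tier applies per-call thresholds (base quality > 25,
MAPQ > 20, mean/median coverage > 30×, ≥ 2 edited reads, editing degree
≥ 10%, removal of 100%-edited calls — likely genomic variants — and a
group-comparison p < 0.05). "Editing degree ≥ 10%" is read as the degree
reaching 10% in at least one group (configurable); the between-group
change reading is available by supplying per-group degree columns.

The stringent tier applies six site-level rules. The fold-change rule is
a two-sided null band: FC ≤ 0.8 **or** ≥ 1.20 (the inclusive boundary at
both edges); a printed inequality chaining both directions is
self-contradictory and the band reading matches the reported discovery
statistics, where surviving sites all fall at ≤ 0.83 or ≥ 1.24.
"Median/mean coverage ≥ 30×" passes if either summary clears the bar. AUC
must strictly exceed 0.7. Removal provenance lists every failed criterion
per site plus a first-failure attribution in the listed order, so
counts always partition the input.

Fold changes are oriented affected-over-reference (DEP/CTRL, BD/UN),
matching the convention in which a control mean of 22% and a case mean
of 18% reports FC ≈ 0.82.

## Differential statistics

Normalization is the rank-based inverse-normal (ordered-quantile)
transform Φ⁻¹((r−½)/n) with average ranks for ties: deterministic,
monotone, and sufficient to make the downstream normality-based test
selection well behaved. (The cited best-of-family transform selection is
per-vector adaptive; a single rank-based map was chosen for determinism —
it is rank-equivalent to any monotone winner of that family.)

Batch adjustment is a parametric empirical-Bayes location–scale model per
batch (ComBat-style), written in-house against the matrix interface this
pipeline needs: the diagnosis group and supplied clinical covariates
(age, sex, treatment and addiction indicators) are protected — estimated
jointly, subtracted before batch-parameter estimation, restored after —
so adjustment cannot absorb the biological signal. Batch location/scale
parameters are shrunk across biomarkers under normal / inverse-gamma
priors (fixed-point iteration, tolerance 1e-8, 100 iterations max).
Because shrinkage deliberately leaves a small residual batch offset, a
final exact recentering removes the per-batch residual means; the module
contract is that post-adjustment residual batch means agree within 1e-8.
Batches need ≥ 2 samples; collinear designs are rejected with the
offending columns named.

Test selection: Shapiro–Wilk on each group at α = 0.05 — if either
rejects, Mann–Whitney; otherwise Bartlett's test at α = 0.05 decides
Student (equal variances) vs Welch. Groups under 3 observations fall back
to Mann–Whitney with a warning. Complete ties yield p = 1 (no evidence of
a shift) rather than an error.

Empirical AUC uses the midrank formula, exactly (concordant + ½·tied)
pairs / (n₁n₀). Orientation is fixed with the affected class positive; an
anti-predictive marker reports AUC < 0.5 rather than being flipped.
Multiple-testing adjustment is Benjamini–Hochberg (via statsmodels),
applied across all biomarkers by default (per-gene adjustment is a
configuration choice). Biomarkers under 80% completeness in either group
are dropped with a warning; remaining missing values are handled
pairwise-complete.

## Target Editing Index

The TEI for a gene is w·x over its significant biomarkers with ‖w‖₂ = 1,
w chosen to maximize empirical AUC on training samples. Because AUC
depends only on the ranking of w·x, the index is identified up to scale;
unit norm fixes it. No additional sign convention is imposed: negating w
maps AUC to 1−AUC, so the orientation is pinned by the maximization
itself (forcing, say, a positive leading weight could destroy the
optimum).

The optimizer is deterministic: candidates are the unpenalized-logistic
direction plus all ± axis directions (so the best single marker is always
in the search space, guaranteeing fitted AUC ≥ best single-marker AUC);
refinement scans, per coordinate, directions cos θ·w + sin θ·eⱼ over a
361-point angular grid, repeating passes until no improvement (≤ 25
passes). The empirical-AUC objective is piecewise constant in direction,
so a grid scan is appropriate where gradients are not. For d ≤ 3 the
optimizer is validated against a dense direction-grid oracle (full circle
/ Fibonacci sphere, 4,000 directions) to within 0.01.

Biomarker significance for TEI membership — and for the classifier's
feature set — is assessed on the *training split only*. In-sample
selection would leak test-set noise into held-out performance; with
training-only selection, null simulations stay at chance.

## MultDS classification

The cohort is split 70/30, stratified, deterministically from the seed
(per-class training counts are round(0.7·n), so proportions hold within
rounding). Each of the ensemble's models draws a balanced set — all
minority-class training samples plus an equal-count majority draw without
replacement — selects mtry by stratified k-fold cross-validated AUC over
an integer grid (CV forests are ntree/10 to keep tuning affordable), then
fits a random forest (scikit-learn; nodesize maps to `min_samples_leaf`,
mtry to `max_features`) on the full balanced set. Package defaults follow
the published grid: 100 models, ntree = 1000, nodesize = 25, mtry
1…min(100, p), 10-fold CV. Ensemble probability is the arithmetic mean
over models; class calls use probability ≥ 0.5 (exact 0.5 is positive).

Randomness derives from a single root seed through `SeedSequence`
substreams, so enlarging the ensemble leaves earlier models unchanged.

Evaluation is on the held-out 30% only (an id shared with training is a
hard error). The AUC CI is the DeLong structural-component asymptotic
interval (clipped to [0,1]); a bootstrap CI would be the natural
alternative but the asymptotic form is deterministic. The operating
threshold is Youden-optimal on *training* probabilities, applied
unchanged to the test set.

The 12 uncertain-diagnosis samples the cohort template includes are
excluded from UN-vs-BD modelling.

## Synthetic data: what it emulates and what it does not

The cohort generator reproduces the structure of a two-step depression
study: group sizes (143 CTRL / 267 DEP; 160 UN / 95 BD / 12 uncertain),
per-group age distributions truncated to the 18–65 inclusion window, sex
ratios, BMI, MADRS / IDS-C30 / YMRS scores (rounded truncated normals),
five psychotropic treatment classes and three addiction flags at the
published prevalences (e.g. antipsychotics 64% in BD vs 36% in UN,
antiepileptics 43% vs 11%), and balanced batch assignment. Severity
bands map MADRS 7–19 / 20–34 / ≥ 35 and IDS-C30 12–23 / 24–36 / ≥ 37 to
low / moderate / severe; when the scales disagree the more severe band
wins (a conservative clinical reading), and scores below both low bands
are "subthreshold".

Site tables model per-sample editing as binomial sampling at the group
rate, with negative-binomial coverage (gamma–Poisson, default mean 1,000×,
dispersion 10) and additive per-batch shifts in percentage points;
probabilities pushed outside [0,1] are clipped with a warning rather than
rejected, keeping extreme-effect simulations runnable. Read simulation
writes 150 nt single-end reads (mirroring a 1×150 bp protocol;
configurable), G at the edited sites of each read's assigned isoform,
uniform substitution errors elsewhere, constant Q37 qualities, and a
per-read truth table.

**Limitations.** Between-patient biological variance beyond binomial
sampling, covariance between sites of one gene, PCR duplicates, indels,
adapter artifacts and alignment errors are not modelled; amplicon
reference sequences are seeded random stand-ins (the real assay sequences
are proprietary). Passing tests therefore demonstrate correctness of the
computational chain and its statistical calibration — not that clinical
cohorts would yield the published performance, which cannot be reproduced
without the undeposited data.

## Problem sizes and determinism

Simulation-based checks run at desk scale chosen to keep the full suite
in minutes while preserving statistical meaning: the end-to-end recovery
harness uses n = 100/100 with 8 genes × 2 biomarkers, 3 genes carrying
effects of 0.8 observed-SD on both biomarkers (observed SD = binomial
plus between-batch variance, the scale on which an analyst would measure
an effect), batch shifts of ±2 points, and a reduced MultDS configuration
(8 models, ntree = 100, mtry grid {2, 4}, 5-fold CV); type-I calibration
uses 10,000 nulls per test path at n = 20/20; read-level exactness uses
20,000 reads per target across the 8-gene panel. Every stochastic
component accepts a seed, and the pipeline report is byte-identical
across runs with the same seed and configuration.

Configuration is YAML parsed into validated dataclasses (invalid
contrasts, fractions, counts or fold-change bands are rejected before any
computation); the run report is JSON with per-stage input/output counts
that cross-check against the stage TSVs.
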