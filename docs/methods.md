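# Methods

This note documents the models, rules and numerical choices behind
`methmark`, and what the synthetic-data generators do and do not
emulate.

## Coordinate and data conventions

All genomic coordinates are 0-based half-open, BED's native
convention; intervals `[a,b)` and `[c,d)` overlap iff `a<d and c<b`.
TSS tables store 0-based positions. A promoter window of a gene on the
plus strand with TSS *t* is `[t−upstream, t+downstream)`; on the minus
strand the window mirrors to `[t−downstream, t+upstream)`, and the
start is clipped at 0. Matrices are pandas DataFrames with unique ids;
missing values are explicit NA, never 0.

## Discovery

**Rank product.** Within each cell line, probes are ranked ascending
by −log2 fold change (rank 1 = strongest upregulation, ties averaged);
RP is the geometric mean of the per-line ranks. The screen is
one-sided (upregulation only) because demethylation re-expresses
silenced genes. The null is built by permuting ranks within lines
(default 1,000 permutations, seeded): `E(g)` is the mean number of
null RPs at or below `RP(g)` per permutation, `pfp(g) = E(g)/rank(g)`
(truncated at 1 for reporting), and the per-probe permutation p-value
is `E(g)/N`. The p-value is uniform under the null; pfp, an FDR
estimate, concentrates near 1 there by construction. For ≤4 probes ×
≤3 lines the permutation engine is validated against exhaustive
enumeration of the `(n!)^K` rank assignments. The screening filter
keeps probes with `pfp < 0.05` and at least two-fold upregulation in a
minimum number of lines; a threshold of 1 for the FDR argument
disables that part of the filter (pfp is truncated at 1, so a strict
comparison would drop pfp = 1 probes).

**Peak mapping and enrichment.** A gene has a promoter peak in a cell
line iff any peak interval overlaps its strand-aware window (defaults
−1,500/+1,000; the enrichment analysis uses −1,500/+500). The
enrichment score is the signed maximum deviation of a running sum that
increments by the (normalised) gene weight at hits and decrements
uniformly at misses (weight exponent 1); significance comes from
permuting gene labels and comparing |ES|, making the p two-sided.

**Differential methylation on counts.** Library size factors are
DESeq-style median-of-ratios against a geometric-mean pseudo-reference
built from all-positive regions. Dispersion is a pooled
method-of-moments estimate: per region and group, `(s²−μ)/μ²` on
normalised counts, pooled by the **mean** across regions — per-region
estimates from 2–4 samples are strongly right-skewed, and median
pooling underestimates the dispersion enough to make the test
anticonservative (observed type-I 0.11 at nominal 0.05; mean pooling
gives 0.052 and recovers a simulated dispersion of 0.1 as 0.092). A
non-positive pooled estimate falls back to Poisson with a warning. The
per-region test conditions on the total count of the two groups: group
sums are negative binomial with means proportional to the summed size
factors and sum dispersion α/n, and the two-sided p adds the
probabilities of all splits no more likely than the observed one.

**Promoter clustering.** Promoter sequences are summarised as
normalised k-mer frequency profiles (default k=6; k-mers containing
ambiguous bases are skipped) and clustered by UPGMA on cosine
distance. Genes are sorted lexicographically before linkage, so the
dendrogram is independent of input order. The distance between two
genes is the number of internal nodes on their leaf-to-leaf path —
siblings are 1 apart, a gene is 0 from itself; this count satisfies
the metric axioms on the leaf set. Candidates are genes fewer than 8
nodes from a known methylation marker, or members of a cluster —
defined as a connected component of the graph joining leaf pairs fewer
than 8 nodes apart — containing at least two genes with at least three
reactivation events. Marker proximity is recorded as the primary
reason when both apply. The k-mer/UPGMA model is this package's
clustering choice; the selection logic on node distances is what the
downstream analysis depends on, and an alternative sequence-similarity
model can be substituted as long as it yields a leaf dendrogram.

## Integration

Each source contributes a dense ranking of its genes. The score of
rank *r* among *N* is `tan((N−r+1)/N)`: the argument decays linearly
from 1 to ~0, giving tan(1) ≈ 1.557 for the best rank and tan(1/N) → 0
for the worst. This interpolation is one natural reading of a
tan(1)-to-0 scale and is injectable (`score_fn`) so alternatives (e.g.
linear in tan(1)) can be swapped. A gene absent from a source scores 0
there. Combined score is the plain sum (equal source weights); final
ties break by the number of sources a gene appears in, then gene id.
The literature/text-mining filter of the original design is replaced
by a user-supplied gene list (network services are out of scope), and
`region_filter` keeps genes whose TSS falls in supplied
copy-number-region intervals.

## MSP calling

A reaction is methylated iff all of: Cq < 35 (strict), |Tm −
Tm_control| ≤ 2 °C (inclusive), |size − size_control| ≤ 10 bp
(inclusive), band height > 20 (strict, instrument units). Inclusive
vs strict follows the rule wording exactly. The size and height rules
can be disabled to emulate the earlier melting-temperature-only
screening phase, which reuses the ±2 °C rule since that phase's
"specific interval" is not quantified. An assay without a positive
control yields invalid calls; a sample whose ACTB control fails to
amplify is invalid throughout; an amplifying no-template control
invalidates its assay for the run. "Informative" assays are those
with at least three methylated **and** at least three unmethylated
samples — the both-ways reading of "(un)methylated in at least three
samples". Prevalence bins (≥75%, 50–75%, 10–50%, <10%) use inclusive
lower edges.

## Statistics

Fisher's exact test is scipy's conditional hypergeometric test for
2×2 tables; for r×c tables all margin-preserving tables are enumerated
(total guarded at 200) and probabilities no larger than the observed
table's are summed (point-probability rule, which reproduces the 2×2
case exactly). Chi-square is Pearson's without continuity correction.
Benjamini–Hochberg adjustment is the standard step-up via statsmodels,
with the family an explicit argument of the caller. Group means carry
t-based confidence intervals. Sensitivity is the methylated fraction
among deceased high-risk patients, specificity the unmethylated
fraction among low-risk survivors.

## Survival

Risk groups use the 12-month age cutoff (365 days): HR-DOD is death
of disease with stage 2/3 + MNA, stage 4 under 12 months + MNA, or
stage 4 over 12 months; HR-SURV is the same high-risk criteria alive
with >1,000 days follow-up; LR-SURV is stage 1/2 single-copy or stage
3 single-copy under 12 months, alive with >1,000 days follow-up;
anything else is unassigned. OS events are disease-related deaths;
EFS events take the earlier of relapse and death. Kaplan–Meier curves
(via lifelines) apply administrative censoring at 2,000 days by
default, mirroring how such cohorts are plotted; the log-rank test is
the Mantel–Cox chi-square, hand-implemented because the stratified
variant (summing observed-minus-expected and covariance over strata
before forming the statistic) is not available in the installed
survival libraries; it is cross-checked against lifelines in the
unstratified case. The Cox model is a single-covariate Newton fit of
the Breslow partial likelihood (|Δβ| < 1e−8, divergence detected at
|β| > 50), reporting the Wald interval and the score statistic at β=0,
which equals the log-rank chi-square for a tie-free binary covariate;
the score test is exposed separately since it exists even when the
MLE diverges (monotone likelihood). Expression dichotomization sends
values below the median to "low", the median and above to "high".

## Classifier

Trees split binary methylation features by Gini impurity, greedily,
with defaults min_split=10, min_leaf=5, cp=0.01 (minimum improvement
as a fraction of root impurity), max_depth=5 — chosen for ~58-sample
binary-feature data and exposed in `CartParams`. Ties break by
feature id and missing calls are routed to the branch holding the
majority of the node's non-missing samples, making refits bit-stable.
No class priors or loss weights are used. Two structural properties
of greedy trees are worth knowing: an XOR-structured feature pair is
invisible to the greedy criterion unless cp=0 (the first split brings
zero improvement), and on pure noise an unpenalised tree will split
anyway — suppressing noise splits without cross-validated pruning
(out of scope) requires a conservative cp around 0.2. Leave-one-out
marker frequency fits one tree per left-out sample and counts a
feature once per tree; the signature is the set reaching 50%
(inclusive), and the restricted leave-one-out predictions feed a
log-rank test between predicted outcome classes.

## qPCR expression

Relative quantities are `E^(Cq_min − Cq)` with efficiency E = 2 unless
provided per assay; the per-assay minimum is the calibrator (the
choice only shifts a global constant). Normalization divides by the
per-sample geometric mean of the reference genes, so any per-sample
additive Cq offset cancels; samples missing a reference are dropped
with a warning. Log transforms use base 2. Mann–Whitney is exact for
tie-free samples with min(n,m) ≤ 8, otherwise the tie-corrected normal
approximation; the two agree to ~0.01 at n=m=8. Kruskal–Wallis uses
the chi-square approximation with k−1 degrees of freedom.

## Synthetic data

The generators emulate the statistical structure of the study, not its
biology or chemistry (no reads, no bisulfite chemistry, no probe-level
intensities):

* **Cohort.** Default sizes 31/28/30 (LR-SURV/HR-DOD/HR-SURV); each
  record is drawn to satisfy its group's defining criteria, so
  reassignment returns the generating labels. Ages use the 12-month
  cutoff; follow-up of survivors is uniform on 1,001–2,400 days.
* **Truth calls.** Default per-group marker frequencies are the
  validation cohort's eight-marker table (e.g. KRT19 0/31, 14/30,
  9/28). `gen_signature_truth` instead plants a complementary
  signature: the deceased high-risk patients are partitioned into one
  block per marker, methylated with probability 0.95 inside and 0.05
  outside its block — markers carry complementary rather than
  redundant prognostic information, which is the regime in which a
  multi-marker panel beats its best member.
* **MSP readouts.** Methylated: Cq ~ N(30, 2), Tm offset N(0, 0.5) °C,
  size offset round(N(0, 2)) bp, log-normal band height; unmethylated:
  no amplification with probability 0.8, else Cq ~ N(38, 1), with Tm
  offset ±|N(4, 1)| °C. Distributions are truncated so that at zero
  flip rate methylated readouts always satisfy and unmethylated
  readouts always violate the call rules — the noiseless round trip
  is exact, and the flip rate is the single error dial.
* **DAC experiment.** Background probes are log-normal with symmetric
  treatment noise; planted genes are silenced untreated (absent calls)
  and reactivate at ≥2.8-fold in most lines (at least three quarters
  of the panel) — a gene methylated across an aggressive cell-line
  panel reactivates wherever it is demethylated. Detection calls flip
  absent→present at a fixed expression threshold.
* **Peaks and counts.** Planted genes carry a 150-bp peak inside
  their promoter window in a designated subset of lines; MNA-specific
  genes only in the MNA lines, with region counts elevated 8-fold
  there (NB, dispersion 0.1); background peaks land in intergenic
  space between the 10-kb-spaced promoters.
* **Survival.** Times are exponential with hazard
  `h0·multiplier^(methylated prognostic markers)` (defaults h0 =
  1/1,500 days, multiplier 4), censored at clinical follow-up; records
  whose clinical outcome is death of disease keep an event at
  follow-up end when the drawn time exceeds it, reconciling the
  constant-hazard model with the cohort's outcome labels.
* **Expression and qPCR.** Tumor expression is log-normal with planted
  genes 4-fold down in high-risk tumors; Cq tables share a per-sample
  offset that reference normalization must cancel.

Every generator is deterministic under its seed. What passing tests on
these data show is that the pipeline's statistics are calibrated and
recover planted effects of the stated sizes; they do not show
robustness to batch effects, assay cross-reactivity, censoring
patterns beyond administrative ones, or marker correlation structures
other than those planted.

## Problem sizes

Tests and the acceptance script run at desk scale: 89-patient
cohorts, 100–1,000 probes, 120–200 promoter regions, 6–8 cell lines,
200–20,000 permutations, and 5–15 replicate simulations per recovery
claim — sizes at which the planted effects are comfortably detectable
and the full suite completes in well under a minute.

## Known limitations

Single-covariate Cox only (multivariable selection is out of scope);
r×c Fisher is guarded enumeration, not a network algorithm; the
clustering model substitutes k-mer/UPGMA for the uncited original
alignment procedure; printed adjusted p-values of the original study
are only approximately reproducible because their correction family
is not stated; and greedy trees without pruning overfit noise unless
cp is raised (see above).
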