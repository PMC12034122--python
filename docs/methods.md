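# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic generator does and does not emulate,
and the known limitations.

## Conventions

Genomic coordinates are 0-based half-open (BED) throughout; any 1-based
numbers are formatting only. All sequences are normalized to the RNA
alphabet (T→U, uppercase) at ingest, so pairing logic is defined on
{A, C, G, U} only. piRNA positions are 1-based from the 5′ end.

## Characterization

Base composition at a position is a per-sample quantity: with
`read_weighted` weighting (the default) each piRNA contributes its read
count in that sample to the base at the queried position of its sequence;
`unique_pirna` weighting gives each expressed piRNA one vote. Read
weighting is the default because group comparisons are made on per-sample
read proportions; the per-piRNA variant is offered for catalog-style
questions. piRNAs shorter than the queried position contribute to no
base; their weight is reported as a coverage deficit rather than being
silently folded into a base class, so fractions always sum to 1 over
covered reads and are NaN (flagged) when nothing covers the position.

Group comparison uses the two-sided Mann–Whitney U test on per-sample
fractions — samples, not reads, are the unit of replication; testing
pooled reads would pseudo-replicate. The exact null distribution is used
when n₁+n₂ ≤ 12 and the pooled values are tie-free (cost grows
combinatorially beyond that); ties or larger samples route to the normal
approximation with tie correction and continuity correction. The two
branches agree within 0.02 at n = 6+6 (checked against full enumeration).

Chromosomal distribution sums size-factor-normalized counts per
chromosome; a piRNA mapped to k loci contributes 1/k per locus (an
unbiased default in the absence of mapping weights), and piRNAs without
loci are reported under `unplaced`.

## Origin classification

A locus is classified by the annotation intervals overlapping at least
`min_overlap_fraction` (default 0.5) of its length. Among qualifying
intervals the highest-priority class wins:

    simple_repeat > LINE > SINE > LTR > DNA_repeat
    > tRNA > rRNA > snRNA > miRNA > lncRNA > pseudogene
    > CDS > UTR5 > UTR3 > intron

Repeat classes come first, structural-RNA classes next, genic features
last, intron after every feature it could host. Ties within a class fall
back to larger overlap, then lexicographic interval name, so the result
is independent of annotation input order. Gene-derived classes require
same-strand overlap by default (sense-derived fragments are the
biological default for translation-machinery-derived piRNAs); repeat
overlap is strand-agnostic. Both the overlap threshold and the
strandedness are configurable. No qualifying overlap means intergenic,
which counts as non-repeat. The summary reports intron separately from
intergenic so either roll-up convention ("genic" vs "non-genic" intron)
can be reproduced downstream.

## Differential expression

The model for piRNA i in sample j is K_ij ~ NB(μ_ij, α_i) with
Var = μ + αμ², log μ_ij = log s_j + β₀ + β₁ x_j (x = case indicator);
log₂FC = β₁/ln 2, case relative to control.

* **Size factors**: median-of-ratios over piRNAs with all-positive
  counts (per-row geometric-mean reference). Factors are meaningful up to
  their ratios; no renormalization is applied. For sparse matrices a
  pseudo-reference over rows detected in ≥ half the samples is available
  behind an explicit flag.
* **Dispersion**: gene-wise method of moments on normalized counts using
  the pooled within-group variance (denominator n−2), so true group
  differences do not inflate α; floored at 1e-8.
* **Fit**: IRLS with weights w = μ/(1+αμ), offsets log s_j, vectorized
  across genes (the two-column design gives closed-form weighted normal
  equations). Max 100 iterations, relative deviance tolerance 1e-8;
  linear predictors clipped to ±30 for overflow safety. Non-converged
  genes are flagged and report the last iterate; all-zero rows are
  flagged with log₂FC 0 and p 1.
* **Wald test**: SE from the expected Fisher information; the two-sided
  p-value uses a **t reference with n−2 degrees of freedom**. With the
  dispersion estimated from the same 20–40 samples, the plug-in normal
  reference is anticonservative (measured ≈ 6.5 % type-I at nominal 5 %,
  n = 14+10, dispersion 0.2); the t(n−2) reference restores ≈ 5 % without
  resorting to shrinkage machinery, and is indistinguishable from the
  normal at the cohort sizes where power matters.
* **Multiplicity and gates**: Benjamini–Hochberg step-up; significance
  requires |log₂FC| ≥ 1 and padj ≤ 0.05 (both configurable).

Deliberately not implemented: dispersion shrinkage toward a mean–variance
trend, outlier (Cook's) handling, independent filtering, shrunken fold
changes, multi-factor designs. These matter most for very small n and
borderline effects; the gates and the calibration checks here are the
intended surface, not parity with any specific reference tool. The
bundled published profile is consumed through the gate-only ingest mode,
which sidesteps questions about the original tool's filtering settings.

## Target prediction

The aligner performs local (Smith–Waterman-style) alignment of the piRNA
5′→3′ against the reverse of an 80-nt transcript window, so columns pair
antiparallel strands. Pair scores: Watson–Crick +5, G:U wobble +1,
mismatch −3; pair scores (not gap penalties) are doubled at piRNA
positions 2–8. Affine gaps cost −9 for the first and −4 for each further
gapped position; adjacent opposite-direction gaps are permitted (the DP
has matched, gap-in-piRNA and gap-in-target states with transitions
between all three). Ties break toward the first cell in row-major order,
so output is deterministic. Under these constants a perfect L-nt duplex
scores 35 + 5L; the sc ≥ 170 gate therefore requires L ≥ 27, which the
synthetic fixtures respect by anchoring on ≥ 28-nt piRNAs.

The binding energy is an additive per-pair proxy — G:C −2.2, A:U −1.1,
wobble −0.6 kcal/mol, nothing for mismatches/gaps — chosen so a typical
~25-bp mixed duplex lands near −40, comfortably resolving the −20
threshold. It is **not** a thermodynamic nearest-neighbor model and
should not be interpreted beyond its gate-keeping role.

Seed filtration counts the longest run of consecutive Watson–Crick pairs
within piRNA positions 2–11 (primary seed, require ≥ 7) and 12–21
(secondary seed, require ≥ 6, truncated for shorter piRNAs). Wobbles are
not Watson–Crick and break runs, as do mismatches, gaps and unaligned
positions; position 1 belongs to neither window. A hit passes overall iff
sc ≥ 170 ∧ en ≤ −20 ∧ both seed runs suffice.

Transcripts are scanned in 80-nt windows stepping 40 (window/step are
configurable; the final partial window is always included), keeping the
best hit per transcript (score, then lower energy, then smaller offset).
Per piRNA, passing transcripts are ranked by score desc / energy asc /
transcript id and capped at 25; the per-piRNA-then-union convention is
used when sets are aggregated.

## Biomarker statistics

AUC is the tie-averaged rank statistic U/(n₁n₂) (the probability a random
case outranks a random control); the ROC curve is traced over distinct
thresholds with ties moving diagonally, so trapezoid area equals the rank
AUC identically. Direction-aware mode (default) reports 1−AUC with the
orientation flag when AUC < 0.5, since both up- and down-regulated
markers are reported on the discriminative scale; a strict mode is
available. The p-value is the Mann–Whitney p of the same comparison
(AUC and U are the same statistic); the 95 % CI is a seeded stratified
bootstrap (2000 resamples) — simpler than DeLong and adequate at these
group sizes. Expression enters as log2(normalized count + 1); the
transform is monotone and thus irrelevant to AUC/Spearman, but it is the
scale recorded for plots.

Spearman correlation is Pearson on tie-averaged ranks; for n ≤ 7 the
two-sided p is exact by enumerating all n! orderings (|ρ| ≥ |ρ_obs| −
1e-12 to absorb float error), otherwise the t approximation with n−2 df.
Zero-variance inputs are flagged rather than returning a spurious ρ.
Binary covariates (metastasis, anaplasia, bilaterality) enter as 0/1.
BH correction is applied across the whole covariate-correlation family;
covariates present in fewer than half the samples are skipped with a
warning.

## Synthetic cohort generator

The generator emulates the structure of the motivating serum cohort — it
is the package's study condition, not a tuning dial:

| parameter | default | rationale |
|---|---|---|
| cohort | 27 cases (14 favorable / 13 unfavorable histology) + 10 controls | published cohort shape |
| piRNAs | 307 | published shared-catalog size |
| library sizes | log-uniform 6,958–369,956 reads | published per-sample range (mean ≈ 95k) |
| baseline abundance | log-normal, σ = 1 | realistic serum skew |
| dispersion | 0.2 | typical bulk small-RNA overdispersion |
| DE spike | 12 up, 22 down, \|log₂FC\| = 2 | published split; central published magnitude (printed range ≈ 1.0–5.3; the minimum would sit exactly on the gate) |
| position-1 composition | control (A,C,G,U) = (.15,.15,.10,.60); case (.15,.35,.10,.40) | canonical 1U pool in controls, elevated 1C in cases |
| position-10 composition | control uniform; case U .35 | elevated 10U in cases, no 10A (ping-pong) bias in either group |
| lengths | 24–34 nt, mode 31 | published spectrum |
| origin read fractions | repeat 4 % (LINE-dominant), tRNA 45 / rRNA 20 / snRNA 14.2, intron 10, intergenic 6.8 | published roll-ups: repeat 4 %, translation machinery 79.2 %, intron+intergenic ≈ 16.7 % |
| chromosome weights | chr1/6/11/16/17 × 2.5 | published dominant chromosomes |
| covariate links | metastasis/anaplasia/bilateral ~ three down-regulated piRNAs, logistic slope −2.5 on standardized log expression | low marker expression raises event probability, the published direction |

Each generator draws from its own named RNG stream (`SeedSequence(seed,
spawn_key=...)`), so adding a generator never perturbs another's output
under the same seed, and each emits a truth table consumed only by tests.
Origin classes are assigned to piRNAs by a deterministic greedy balance on
expression shares (largest share → largest remaining class deficit), so
realized read fractions track the configured targets within sampling
noise; every locus is planted wholly inside a dedicated same-strand
annotation interval (or an unannotated gap for intergenic truth), and
annotations never overlap — which is what makes 100 % class recovery the
correct closed-loop expectation. Target fixtures per anchor piRNA:
a perfect reverse complement (pass), a primary-seed mismatch at position 8
(run 6, fail), a secondary-seed mismatch at position 17 (run 5, fail), and
a G:U wobble inside the primary seed (fail despite a near-perfect score);
expected verdicts are computed from the construction arithmetic, not from
the aligner.

What the generator does **not** emulate: read-level errors and adapter
artifacts, multi-mapping ambiguity (each piRNA gets one locus by
default), overlapping/nested annotations, correlated piRNA expression,
batch effects, and composition–expression coupling (group-specific base
composition is exercised through per-sample pools, while the integrated
cohort uses one shared sequence catalog). Passing closed-loop tests
therefore demonstrates the correctness of the pipeline's arithmetic under
the stated model, not robustness to these real-data complications.

## Problem sizes used in validation

Closed-loop validation runs the full default cohort (307 × 37) with 10
target-fixture anchors (40 transcripts); calibration uses 2,000 null
genes at n = 14+10, dispersion 0.2, and 500 replicate genes with planted
log₂FC = 2 at dispersion 0.1, n = 10+10; oracle equivalence suites use
500 random ≤ 8-nt sequence pairs (exhaustive alignment enumeration),
10,000 random pairing masks, 1,000 small AUC instances, and full
enumeration for Mann–Whitney (n ≤ 12) and Spearman permutations (n ≤ 7).
These sizes give the checks their statistical meaning (e.g. binomial SE
≈ 0.5 % on a 5 % type-I rate at 2,000 genes) while keeping the whole
suite fast.

## Known limitations

* The NB pipeline is a transparent simplification; results on very small
  or very sparse cohorts will differ from shrinkage-based tools, and padj
  values for the bundled published profile are taken as printed rather
  than recomputed (the raw data is not part of this package).
* The duplex energy model is additive, not thermodynamic; energies are
  comparable within this package only.
* The null distribution of the direction-aware AUC is folded (always
  ≥ 0.5); its CI and p-value describe the oriented comparison.
* Exact branches (Mann–Whitney, Spearman permutation) are combinatorial
  and intentionally capped at small n.
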