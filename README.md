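# pirnascope

Analysis pipeline for circulating (serum) piRNA sequencing cohorts:
positional nucleotide-bias and length characterization, genomic-origin
classification, negative-binomial differential expression, seed-filtered
piRNA→mRNA target prediction, and diagnostic biomarker statistics.

PIWI-interacting RNAs (piRNAs) are 24–31 nt small non-coding RNAs best
known for transposon silencing in the germline, but in somatic fluids they
derive largely from non-repeat sources (tRNA/rRNA/snRNA fragments, genic
and intergenic loci) and show disease-associated expression changes. This
package implements the downstream analysis of such a cohort — everything
after the count matrix — for case/control serum small-RNA studies (the
motivating design: a pediatric renal-tumor cohort of 27 patients and 10
healthy controls over 307 serum piRNAs), together with a fully seeded
synthetic-data generator that emulates the cohort structure with known
ground truth, so every stage can be validated closed-loop without access
to patient data.

## What it computes

* **Characterization** — per-sample base fractions at piRNA positions 1
  and 10 (1U / 10A bias diagnostics), read-length spectra, chromosomal
  distribution of normalized expression; group differences by two-sided
  Mann–Whitney U on per-sample fractions (exact null for n₁+n₂ ≤ 12
  without ties, tie/continuity-corrected normal otherwise).
* **Origin classification** — each piRNA locus is assigned the
  highest-priority annotation class covering ≥ 50 % of the locus
  (repeat classes ≻ structural RNAs ≻ genic features; no overlap ⇒
  intergenic); repeat-related ⇔ class ∈ {LINE, SINE, LTR, DNA repeat,
  simple repeat}. Multi-locus piRNAs split reads 1/k.
* **Differential expression** — median-of-ratios size factors s_j,
  gene-wise method-of-moments dispersion α, two-group NB GLM
  K_ij ~ NB(μ_ij, α), log μ_ij = log s_j + β₀ + β₁·case_j, fitted by
  IRLS; Wald statistic β̂₁/SE(β̂₁) with a t(n−2) reference,
  Benjamini–Hochberg adjustment, and the significance gates
  |log₂FC| ≥ 1 ∧ padj ≤ 0.05. An ingest mode applies the gates to any
  precomputed log₂FC/padj table.
* **Target prediction** — miRanda-style local duplex alignment of the
  piRNA 5′→3′ against the reversed transcript window (WC +5, G:U wobble
  +1, mismatch −3, affine gaps −9/−4, pair scores ×2 at positions 2–8),
  an additive per-pair binding-energy proxy (G:C −2.2, A:U −1.1, wobble
  −0.6 kcal/mol), and the seed filtration requiring ≥ 7 consecutive
  Watson–Crick pairs in the primary seed (positions 2–11) and ≥ 6 in the
  secondary seed (12–21); hits gated at sc ≥ 170 and en ≤ −20, top 25
  targets per piRNA.
* **Biomarker statistics** — per-marker AUC via the tie-averaged rank
  formula U/(n₁n₂) with stratified-bootstrap 95 % CI and Mann–Whitney p;
  Spearman rank correlations against clinicopathological covariates with
  exact permutation p for n ≤ 7.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (seed 0):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_characterize_pirnaome.py
python analysis/03_classify_origins.py
python analysis/04_differential_expression.py
python analysis/05_predict_targets.py
python analysis/06_biomarker_statistics.py
```

which prints, among other lines:

```
cohort: 307 piRNAs x 37 samples
library sizes 7160-346372 reads (mean 95571)
modal read length: 31 nt
per-sample position-1 C fraction, case vs control (grouped pools): U=270, p=4.14e-06, medians case/control = 0.355/0.148
repeat-related reads: 4.07% (mean per sample)
translation machinery: 78.68%; intron+intergenic: 17.25%
synthetic: 34 significant (12 up, 22 down); recall 100.0%, empirical FDR 0.000
published profile: 34 significant (12 up, 22 down); down log2FC -5.340..-1.105, up 1.025..1.777
planted filter verdicts reproduced: 40/40
planted biomarker piR-sim-0019: AUC 0.9481
```

Reading the output: the simulated serum pool peaks at 31 nt; cases show
the planted elevation of cytosine at position 1 (fraction 0.355 vs 0.148,
Mann–Whitney p ≈ 4×10⁻⁶ across samples); ~4 % of reads are repeat-derived
and ~79 % come from translation-machinery RNA fragments; the NB-Wald stage
recovers all 34 planted differentially expressed piRNAs with no false
calls; the seed filters reproduce every planted target verdict; and the
planted diagnostic marker separates cases from controls with AUC 0.95.
The "published profile" line is the package's gate arithmetic applied to
the bundled 34-piRNA serum profile
(`src/pirnascope/data/wt_serum_depirna.tsv`).

The same stages are available as a CLI (`pirnascope simulate / characterize /
classify-origins / de / targets / biomarkers / run`), e.g.

```bash
pirnascope simulate --seed 0 --out cohort/
pirnascope de --counts cohort/counts.tsv --meta cohort/meta.tsv --out de/
```

## Layout

```
src/pirnascope/      library modules (io_core, characterization,
                     origin_classify, diffexpr, target_predict,
                     biomarker_stats, synthetic_data, pipeline, cli)
analysis/            numbered narrative drivers writing under results/
tests/               pytest suite (unit, property and end-to-end checks)
scripts/acceptance.py headline-quantity reproduction
docs/methods.md      models, parameters, numerical choices, limitations
```
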