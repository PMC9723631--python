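# Methods

This document specifies the statistical model behind each pipeline
stage, the synthetic-data generator that exercises it, and the
numerical conventions. Everything here is implemented in
`src/pgxeqtl/`; every routine has an independent oracle in `tests/`.

## 1. Statistical model

### 1.1 Drug-response phenotype

Raw counts per condition are normalized to log2 counts-per-million
with a 0.5 pseudocount:

```
log2CPM = log2( (count + 0.5) / (library_size + 1) · 1e6 )
```

The per-line drug response of gene *g* in line *i* is the paired
contrast

```
r_ig = log2CPM(drug)_ig − log2CPM(vehicle)_ig
```

Any additive per-(line, gene) effect shared across conditions —
baseline genotype main effects, clone-to-clone expression offsets —
cancels exactly in `r`, which is why the design needs no covariate
model.

### 1.2 Genotype quality control

A SNP enters the scan if it passes all of:

* **call rate** > 0.95 over lines,
* **Hardy–Weinberg** exact-expected chi-square (1 df) p > 0.001,
* **MAF ≥ q\*** where `q*` is the smallest frequency giving one
  expected minor-allele homozygote, `n·q² = 1` ⇒ `q* = √(1/n)`,
  rounded to two decimals and capped at 0.50. At n = 30,
  `√(1/30) = 0.1826 → 0.18`. The rationale: the three-class ANOVA is
  meaningless without an expected observation in the rare homozygote
  class.

Missing dosages are never imputed; each pair's test drops lines with
a missing call for that SNP.

### 1.3 PGx-eQTL scan

Candidate pairs are (SNP, gene) with the SNP inside a condition's
receptor ChIP-seq peak padded by ± 500 bp and within ± 200 kb of the
gene body (distance 0 inside the body; boundaries inclusive at exactly
200 kb). For each pair, `r` is split by genotype class {0, 1, 2} and
tested by **one-way ANOVA** (F statistic, between/within mean squares,
p from the F distribution). A class with fewer than `min_class_size`
(default 2) observations makes the pair *not testable* (reported, not
silently dropped); an optional `merge_sparse` mode merges the rare
homozygote into the heterozygote class instead. Benjamini–Hochberg
FDR is computed over the tested pairs of each condition; a PGx-eQTL
requires q < 0.05 **and** baseline silence (external baseline-cohort
p > 0.05, or not reported — controlled by
`missing_baseline_is_silent`, default true). A discovered pair is
additionally flagged `antagonist_lost` when its nominal p under
agonist + antagonist co-treatment exceeds 0.05. Post-hoc pairwise
contrasts use the Tukey–Kramer studentized-range test.

### 1.4 Reporter (STARR/MPRA) tests

*Variant level.* Replicates are pooled by summing counts. For each
variant and condition pair (vehicle, drug) the 2×2 table
`[[ref_v, alt_v], [ref_d, alt_d]]` is tested with a two-tailed Fisher
exact test. The allelic shift is
`Δ% = 100·(alt_d/total_d − alt_v/total_v)`. A call requires BH
q < 0.05 and |Δ%| > 10. Variants are excluded up front when they are
indels, multi-allelic, or have pooled total < 20 in either condition.

*Locus level.* With two replicates a per-locus t test has 2 residual
degrees of freedom and cannot reach q < 0.05, so the activity test
pools the residual variance across all loci (the moderated-test family
strategy): per-locus log-CPM means per condition, a common pooled
variance with `Σ_loci (n_v − 1 + n_d − 1)` df, and a t statistic per
locus. Because a sizeable induced subset biases CPM itself (the
library-size denominator grows), log-CPM values are first re-centred
by a DESeq-style **median-of-ratios** offset per replicate, which is
valid when the majority of library fragments are unchanged.

### 1.5 Chromatin states

A 25-state segmentation (consumed, not learned) maps each SNP to the
half-open tile containing it; gaps yield NaN with a warning. Per-state
enrichment is a one-sided binomial test of the hit count against the
state's bp share of the segmented genome (default), or a
hypergeometric test against an explicit background SNP set. States
collapse to four categories (Promoter, Enhancer, Transcribed,
Repressive/Repetitive/Unknown) plus a looping-enhancer flag.

### 1.6 Loops

Loop lists are 5 kb-binned BEDPE with counts and FDR per condition.
Validation keeps cis loops with span ≤ 2000 kb (inclusive),
FDR < 0.01, and at least one anchor overlapping an H3K27ac peak. A
gene's anchor target is its body extended 2000 bp past the 5′ end,
strand-aware, clipped at 0. Connectivity between a SNP bin and a gene
bin is **direct** (one loop joins them) or **common contact** (two
loops share one intermediate anchor); direct takes precedence. Loop
dynamics between vehicle count *v* and drug count *d*:

```
induced      v = 0 ∧ d > 1,  or  d/v > 1.5
repressed    mirror image
constitutive v > 0 ∧ d > 0 and neither fold criterion
absent       otherwise (including the bare 0 ↔ 1 transitions,
             which single-count evidence cannot support)
```

### 1.7 Clinical catalogs

LD expansion is one hop at r² > 0.8 (strict), symmetric, always
including the index SNP. A discovered SNP overlaps the GWAS/PheWAS
catalog directly or through a proxy (reported with `proxy_of` and the
proxy r²); optional filters restrict to genome-wide-significant
catalog rows or a maximum p.

## 2. Hand-implemented statistics (`pgxeqtl.stats`)

The primitives are written from their definitions; `scipy.stats` is
used only for distribution CDFs/PMFs (F, t, chi-square,
hypergeometric, studentized range, binomial).

* **Fisher exact (two-tailed)**: sum of hypergeometric probabilities
  ≤ observed mass × (1 + 1e-7) — the R/scipy probability-mass
  convention; log-gamma arithmetic for stability.
* **Benjamini–Hochberg**: step-up with cumulative-minimum
  monotonicity; NaN p-values are excluded from m and returned as NaN.
* **Tukey–Kramer**: q statistic with unbalanced Kramer correction;
  for k = 2 the p-value reduces exactly to the pooled two-sample t via
  `p = 2·T_df.sf(q/√2)` — a closed-form identity used as an
  equivalence check.
* **HWE**: chi-square against expected counts from the estimated
  allele frequency, 1 df.
* **ANOVA, Pearson r, paired t, hypergeometric enrichment, ΔΔCt**:
  textbook formulas; cross-validated against `scipy.stats.f_oneway`,
  `tukey_hsd`, `fisher_exact` and `statsmodels` `multipletests` in the
  test suite, plus brute-force enumeration oracles (factorial-free
  Fisher enumeration for all tables with margins ≤ 60; exhaustive
  connectivity search for loop graphs with ≤ 10³ edges).

## 3. Synthetic-data generator (`pgxeqtl.simulate`)

### 3.1 Layout and genotypes

A toy genome of 2 × 10 Mb chromosomes carries `n_genes` (default 500)
genes on a regular grid and `n_snps` (default 2000) SNPs, each
anchored to one gene at a random offset with |offset| ∈ [20 kb,
180 kb] — distal regulatory placement that keeps the designated pair
inside the ± 200 kb window while guaranteeing SNP and promoter occupy
distinct 5 kb loop bins. Genotypes are binomial(2, MAF) under HWE,
MAF ~ U(0.05, 0.5); 10 % of SNPs are true PGx-eQTLs with
MAF ~ U(0.25, 0.5) (a power consideration: an interaction detectable
at n = 30 needs populated homozygote classes, and common regulatory
variants are the realistic discovery set at this cohort size).
Deliberate QC violators: 2 % HWE violations (het-depleted), 2 %
low-call-rate SNPs.

### 3.2 Expression and the noise model

Counts per (line, gene, condition) are negative binomial around

```
log2 μ = log2 b_g  + 1{drug} · δ_g(condition)
       + L_ig                       (line effect, sd 0.4)
       + β/2 · G_ij · a(condition)  (interaction, true pairs only)
       + ε                          (per-condition, sd σ_e/√2)
```

with baseline mean `b_g ~ U(100, 1000)`, drug effect `|δ_g| ∈ [1, 3]`
for 30 % of genes (attenuated ×0.4 for the modulator alone, ×0.2
under co-treatment), and interaction slope β = 2 (hom–hom log2-ratio
difference) with condition scaling `a = 1` for the agonist, `a = 0.4`
for the modulator alone (partial agonism — the modulator weakly
unmasks the same variants, yielding a smaller discovery set), and
`a = 0` under co-treatment (full antagonism — this is what makes
discovered pairs lose their association).

The noise structure encodes the paired design: the biological line
effect `L_ig` is drawn once per (line, gene) and shared across
conditions, so it cancels in the drug/vehicle response; the remaining
technical overdispersion is a small NB dispersion (φ = 0.01); and the
per-condition ε has sd `σ_e/√2 = 0.3/√2` so the response residual
`ε_d − ε_v` has sd σ_e = 0.3. Decoy baseline eQTLs (5 % of SNPs)
carry a genotype main effect in every condition, which cancels in the
response — they test baseline silence, not power.

### 3.3 Assay layers

* **Peaks**: ± 150 bp around every true SNP in the agonist set, 85 %
  shared with the modulator set, 200 background peaks, plus an
  independent-antibody replicate set retaining 70 % of peaks (with
  jitter) for the reproducibility analysis. 15 % of decoy SNPs are
  placed in peaks so the scan sees null pairs.
* **Segmentation**: a 25-state tiling; true SNPs are placed into
  enhancer states at the configured fractions (81 % enhancer, 41 %
  looping-flagged).
* **Reporter counts**: allele-resolved counts at depth ~400× per
  variant/condition, 2 replicates; 50 % of assayed variants carry a
  0.25 allele-fraction shift under drug; spiked indel/multi-allelic/
  low-depth records exercise the filters. The locus library adds 1000
  inactive background fragments so the median-of-ratios estimator's
  unchanged-majority assumption holds (as in a real STARR library,
  where most fragments are inert).
* **Loops**: per true pair a direct or common-contact (20 %) path at
  5 kb bins with class mix 86 % constitutive / 6 % induced / 8 %
  repressed, plus 400 decoy loops and 10 % invalid-anchor loops.
* **Catalogs**: 25 % of true SNPs overlap a GWAS/PheWAS catalog, 30 %
  of those only via an LD proxy at r² ≥ 0.8; baseline-cohort p-values
  are reported small for decoys, uniform for the rest, and missing for
  a subset.

### 3.4 Realism and limits

The generator reproduces the *statistical* structure the pipeline must
handle — paired responses with shared biological variance, interaction
unmasking and antagonist nullification, composition bias in reporter
libraries, QC failure modes, half-open boundary cases — not biological
sequence realism. Known simplifications: no LD structure among
discovery SNPs (each SNP is anchored to one gene; LD exists only in
the catalog layer), no trans effects, interaction strictly additive on
the log scale, a single β for all true pairs, NB dispersion constant
across genes, and a uniform toy genome with no mappability or GC
structure. Consequences worth knowing: empirical FDR estimates from
truth tables are slightly conservative because near-threshold decoys
are scarce, and loop-dynamics truth is exact by construction, so the
confusion matrix tests the rule, not noise robustness.

## 4. Numerical and engineering conventions

* **Coordinates**: 0-based half-open everywhere internally; SNP `pos`
  is 1-based (`start = pos − 1`). Interval queries use one interval
  tree per chromosome with strict ≥ 1-bp-overlap semantics, verified
  against brute force.
* **Determinism**: every stochastic routine takes a seed and uses
  `numpy.random.default_rng`; JSON output is written with sorted keys
  and TSVs with fixed column order, so identical configs produce
  byte-identical output trees (checked file-by-file in the acceptance
  script).
* **Fisher tolerance**: the two-tailed mass comparison uses a
  relative tolerance of 1e-7 to absorb floating-point ties, matching
  the scipy/R convention.
* **NaN policy**: missing dosages drop pairwise per test; NaN
  p-values propagate through BH as NaN without affecting other
  entries; empty inputs return NaN-valued summaries rather than
  raising, except where the input is structurally invalid (which
  raises with the offending file/line).
* **Pipeline errors** are wrapped in `StageError` naming the stage
  (`[simulate] …`), and the CLI maps config errors to exit code 2 and
  stage failures to exit code 3.
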