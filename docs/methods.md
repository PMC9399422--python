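# Methods

## Cohort model and rationale

The pipeline targets extreme-phenotype designs: small groups chosen at
opposite clinical extremes (here, immediate-onset diabetic retinopathy,
retinopathy-free long-duration diabetes, and late-onset retinopathy;
reference sizes 6/5/4).  The premise is that rare, strongly deleterious
germline variants are enriched at the extremes, so gene-level *carrier
rates* — not per-variant association — are the unit of comparison.  All
inference is descriptive and threshold-based; no asymptotic test is
attached to the rate differences, because at n ≤ 6 per group no such test
would be calibrated.

## Candidate filter

A variant passes iff

```
protein_altering(class) AND (  (SIFT <= sift_max AND all AFs < af_max)
                            OR ClinVar in {pathogenic, likely_pathogenic} )
```

* `sift_max = 0.05`, inclusive; `af_max = 0.05`, strict, required in all
  three population databases simultaneously (1000g 2015aug all,
  esp6500siv2 all, ExAC EAS).
* Missing AF ⇒ rare (default): an allele unobserved by a population survey
  cannot be established as common.  A strict alternative
  (`missing_af_policy="treat_as_fail"`) is provided.
* Indels with no SIFT score are exempt from the deleteriousness clause by
  default (SIFT is undefined for most indels), so they qualify on class +
  rarity or ClinVar; `missing_sift_policy_indel="fail"` disables this.
  SNPs with no SIFT score fail the clause.
* The ClinVar route is independent of SIFT/rarity by default but still
  requires the protein-altering class gate.  Both choices are flags
  (`clinvar_rescue_independent`, `clinvar_requires_class`) because the
  clause precedence in prose descriptions of such filters is ambiguous;
  the default reads ClinVar as a stand-alone evidence route.

Failure reason codes are assigned in gate order — class, then SIFT, then
AF — so a variant violating exactly one clause gets that clause's code;
a variant violating several gets the first.

## Collapsing and rate calls

`M[g, s] = 1` iff sample *s* carries ≥ 1 candidate in gene *g*; the
per-cell provenance retains every contributing (chrom, pos, ref, alt) key.
Group denominators are group sizes — all samples are assumed assayed for
all genes; no per-gene coverage adjustment is attempted because exome
coverage metadata is not part of the input contract.

Rate thresholds (true ≥ 3/5, false ≤ 2/5, DMG gap ≥ 3/5) are evaluated in
exact integer/rational arithmetic (`5k ≥ 3n`, `Fraction` differences).
This matters: the calls are the pipeline's central binary statistic and
`0.6` is not representable in binary floating point.  Thresholds supplied
as decimals are mapped to rationals via `Fraction(x).limit_denominator(1e6)`.
The indeterminate band (2/5, 3/5) is reported as such, never coerced.

## DMG classification

For comparisons (case, control), a DMG's `enriched_in` is the group with
the larger rate.  Enrichment in any case group ⇒ susceptible; in the
control group ⇒ protective; otherwise unlabeled.  Default comparisons are
each retinopathy group versus the retinopathy-free control.

## Correlation network

Pearson r between binary carrier profiles across the pooled cohort
(n = 15 by default); per-group correlation at n ≤ 6 is not meaningful and
is deliberately not implemented.  p is the two-sided t-transform with
n − 2 df; |r| = 1 maps to p = 0.  Edges require |r| ≥ 0.8 and p < 0.05 on
the raw p by default — a Benjamini–Hochberg option exists but is off,
matching the descriptive intent of the network.  Zero-variance genes
(carriers in all or no samples) yield no edges and are logged.

## Clustering

Jaccard distance on binary profiles, average linkage (UPGMA over the
original leaf distances).  Binary profiles produce many exactly tied
distances, so determinism requires an explicit rule: candidate merges are
ranked by (distance, smaller cluster id, larger cluster id), with leaves
numbered 0..n−1 and merged clusters numbered onward in creation order.
Cluster distances are computed with exactly-rounded summation
(`math.fsum`), making ties well-defined regardless of accumulation order.
Two all-zero profiles get distance 0.  The implementation is an in-package
O(n³) agglomerator — fine at cohort scale (n ≤ tens) and necessary because
off-the-shelf linkage routines do not guarantee this tie-break.

## Cross-verification

Variant identity is the normalized key (chrom without "chr", pos,
upper-case ref/alt); no indel re-alignment is performed, so left-alignment
conventions must match between the WES and RNA callers.  Same-patient
RNA-seq verification is sample-matched by default; external gene sets are
compared sample-agnostically at the gene level.  A panel gene is verified
by ≥ 1 verified candidate variant in ≥ 1 sample.

## DEG selection

Strict thresholds exactly as conventional: p < 0.05 and ratio-scale fold
change > 2 or < 0.5.  `basic_two_group_stats` — counts-per-million with a
pseudocount of 1, fold change as the ratio of group means, p from Welch's
t on log2 values — is a *stand-in* for a dispersion-modelling DE method,
present only so synthetic runs are self-contained; its output is flagged
accordingly and externally computed (gene, fold_change, p_value) tables
are the intended production input.  Intersections are stratified by
direction; a gene up in one comparison and down in another is never
"shared".

## Synthetic cohort generator

What it emulates: per-sample ANNOVAR-style variant tables whose
annotations land in the filter's pass/fail regimes; planted DMGs with
exact per-group carrier rates; Poisson-distributed multiplicity of
variants per carrier (multiple sites in one gene of one sample, mean 1.3);
RNA-seq variant subsets at a configurable concordance (default 0.33,
reflecting roughly one-third SNP concordance between platforms);
negative-binomial counts (variance m + φm², default φ = 0.1, baseline
mean 100) with planted fold changes; and external gene sets with known
panel overlap.

Key design choices:

* **Exact-count planting** — planted carrier sets are drawn as exactly
  round(rate × n) samples, so intended rates are realized exactly and
  threshold tests are not confounded by Bernoulli noise.  A rate whose
  product with the group size is not an integer is an error, not a silent
  rounding.  Background genes use Bernoulli(0.05) draws per (gene, sample).
* **Single-clause decoys** — each decoy variant violates exactly one
  filter clause (synonymous class, SIFT > 0.05, or one AF ≥ 0.05), so
  every reason code is exercised and attributable.  Decoys are placed only
  in background genes, never in planted DMGs.
* **Labelled sub-streams** — each artifact (WES, RNA, counts, external
  sets) draws from its own generator derived from the master seed via a
  fixed spawn key, so adding an artifact never perturbs the others, and
  identical seeds give byte-identical files.

What it does **not** emulate: linkage disequilibrium, zygosity, per-gene
coverage variation, annotation errors or version drift in SIFT/AF/ClinVar,
batch effects or library-size imbalance in counts, and indel
representation ambiguity.  Passing tests therefore demonstrate the
*logic* of the pipeline — filter semantics, exact threshold behaviour,
recovery of planted structure — not robustness to those real-data
artifacts.

## Problem sizes and calibration behaviour

Validation runs use 5,000 background genes × 15 samples × 20 seeds for
DMG recovery, ~5,000-variant tables for filter-oracle equivalence, 10,000
variants for concordance calibration, and 100 replicates of a 2,050-gene
count matrix for DEG recovery — sizes at which binomial noise is well
characterized while a full run stays interactive.

One calibration fact worth knowing: with background carrier rate 0.05 and
groups of 6/5/4, a background gene crosses the 0.6 rate-difference cut
with probability ≈ 1.3 × 10⁻³ (dominant term: ≥ 3/5 case carriers,
P ≈ 1.1 × 10⁻³, times 0/6 control carriers, P ≈ 0.74).  Over 5,000
background genes this yields ~6–7 false DMGs per cohort in expectation.
Recall of strongly planted genes (gap ≥ 0.8) is exact, but precision
against a 40-gene planted panel settles near 0.86 — an intrinsic property
of thresholding carrier-rate differences at these group sizes, and the
reason the method is a screen whose output panel needs orthogonal
verification (the RNA-seq and external-cohort stages) rather than a
calibrated test.

## Limitations

* Rate thresholds are hard cuts; genes straddling a boundary by one
  carrier flip between calls.  The indeterminate band surfaces some of
  this, but sensitivity analysis over thresholds is the user's job (all
  cuts are parameters).
* The network p-values are raw and descriptive, not FWER/FDR-controlled
  by default.
* The DE stand-in underestimates dispersion uncertainty relative to
  negative-binomial models; do not interpret its p-values at face value on
  real data.
* No liftover, no reference validation, no annotation computation:
  SIFT/AF/ClinVar values are consumed as given.
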