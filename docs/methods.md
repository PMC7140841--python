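# Methods

## Scientific setting

`repair-carrier` models a case/control germline burden analysis of rare,
potentially damaging variants in DNA-repair genes, of the kind used to ask
whether men with lethal prostate cancer carry protein-truncating mutations in
genes such as *ATM*, *CHEK2* or *BRCA2* more often than unselected patients
or population controls. The package covers the post-variant-calling stages
only: hard quality filters, variant prioritisation into damaging tiers,
carrier counting, and exact association tests. Alignment, duplicate marking,
variant calling, quality-score recalibration and annotation (ANNOVAR, CADD,
REVEL, ClinVar) are upstream concerns whose outputs are consumed as input
fields, never recomputed.

## Quality filters

Two hard-filter stages mirror standard exome QC practice:

* **Sample level** — a sample is excluded when less than 30% of its target
  bases are covered by at least 20 reads (`min_frac_bases_20x = 0.30`,
  strict less-than; a sample at exactly 30% is kept). All of the sample's
  calls are removed with it.
* **Call level** — a genotype call is retained iff it passed upstream
  variant-quality recalibration (`PASS` flag, consumed not computed), its
  allele fraction is ≥ 0.3, its read depth at the site is ≥ 12, and its
  readPosRankSum (if annotated) is > −1.7. The three conditions form a
  single conjunction, so application order is irrelevant and the filter is
  idempotent.

An **absent readPosRankSum is non-disqualifying**. The annotation is
routinely missing for homozygous and indel calls; requiring it would silently
discard most frameshift variants, which contradicts the observed content of
real damaging-variant tables. "Coverage" in the call filter is read as
per-sample depth at the call site, consistent with the surrounding
call-level rules.

## Variant prioritisation (tiering)

Applied per variant, in order, with default thresholds
`max_maf = 0.01`, `min_cadd = 20`, `min_revel = 0.75`:

1. **Exclusion pre-filter** — off-panel gene, intergenic location, or
   reference-population MAF strictly above 0.01. An absent MAF is *not*
   evidence of commonness: rare variants are precisely those most likely to
   be unobserved in reference populations.
2. **Benign precedence** — any benign / likely-benign ClinVar assertion
   with no coexisting pathogenic / likely-pathogenic (P/LP) assertion is
   neutral regardless of scores.
3. **Tier 1** — protein-truncating variants (stopgain, frameshift
   insertion/deletion, splice-altering) with CADD phred ≥ 20 *or CADD
   unannotated*, supported either by a ClinVar P/LP assertion or by a flag
   that the truncation disrupts a UniProt-reported protein domain.
4. **Tier 2** — missense single-nucleotide variants with a ClinVar P/LP
   assertion, or with CADD phred ≥ 20 *and* REVEL ≥ 0.75.
5. Otherwise neutral.

Three decisions here were genuinely open and are the package's own:

* **Missing CADD passes the Tier 1 CADD condition.** CADD phred is
  typically not emitted for indels by annotation pipelines; treating absence
  as failure would exclude essentially all frameshift variants, which is
  inconsistent with published damaging-variant tables in this field (five
  of the eleven truncating variants in the packaged fixture have no CADD
  value yet are Tier 1).
* **Multi-submitter ClinVar strings** ("5,4,3") are a set of assertions;
  any 4/5 code makes the variant P/LP, and benign precedence applies only
  when no P/LP code coexists. This reproduces every fixture row, including
  mixed "5,4,3" and "5,3" missense variants assigned Tier 2 by the P/LP
  route despite sub-threshold REVEL.
* **`disrupts_domain` is an input annotation**, not a UniProt query;
  absence is treated as false. Operationalising "truncation before or
  within a protein domain" (domain database version, transcript choice) is
  delegated to the annotating user.

All score comparisons are inclusive (≥) and the MAF cut is strictly
greater-than, matching the way such thresholds are conventionally stated.

## Carrier counting and association

* **Cases** (per-individual genotypes): a carrier is an individual with at
  least one qualifying variant of the tier; an individual with several
  qualifying variants counts once. Rate = carriers / cohort size.
* **Controls** (ExAC-style allele-count summaries): per gene, the carrier
  count is the sum of allele counts over qualifying variants, under the
  assumption that each individual carries at most one deleterious mutation
  per gene — a slight overestimate for very common genes. The pan-gene
  "ALL" row sums per-gene counts for controls (possible double-counting of
  individuals mutated in two genes, documented rather than corrected) but
  counts distinct individuals for cases. Per-gene denominators default to
  the single cohort-level covered-persons value; rows disagreeing on it are
  rejected.
* **Association**: two-sided Fisher's exact test by the minimum-likelihood
  convention — the p-value sums hypergeometric point probabilities of all
  2×2 tables with the observed margins whose probability does not exceed
  the observed table's, with a 1e-7 relative tie tolerance. The
  implementation computes the hypergeometric log-pmf over the support
  directly (vectorised, renormalised in linear space), which keeps the
  exhaustive enumeration cross-check affordable; it is validated in tests
  against exact integer-arithmetic enumeration over every table with grand
  total ≤ 60 and against an independent library implementation on random
  tables. No multiple-testing adjustment is applied — the analysis design
  reports unadjusted per-gene and pan-gene p-values.
* **Expected carriers**: `rate × n`, for projecting an externally reported
  carrier rate onto a cohort of size *n*.

Report rendering rounds rates to two decimals (as percentages) and
p-values to three decimals, with values below 0.0005 rendered `<0.001`.
Rounding is applied at output only; tests compare unrounded values and then
round. The published record this package reproduces contains one internal
inconsistency in two headline p-values (0.030/0.040 in a summary versus
0.003/0.004 in the full results table, which the printed contingency tables
confirm); the package targets the table values.

## Synthetic cohorts

The generator emulates the study-shaped data the analysis assumes, so the
pipeline is fully testable without protected sequencing data. It does **not**
simulate reads, linkage, relatedness or population structure; passing tests
demonstrate correct behaviour of the filtering/classification/association
machinery under the stated sampling model, not robustness to those
real-data complications.

* Per individual and gene, Tier 1 / Tier 2 carrier status is independent
  Bernoulli at configured rates (defaults: the per-gene rates observed in
  the 122-man lethal cohort, e.g. *ATM* 4/122, *CHEK2* 5/122). Carriers
  receive a variant from a per-gene catalog whose annotations are built by
  **inverting the classifier's rules** (each score drawn from the required
  side of its threshold), so every intended-tier variant is classified as
  intended — a deterministic generator–classifier contract rather than
  rejection sampling.
* Noise variants (common MAF, ClinVar-benign, sub-threshold scores,
  off-panel, intergenic) exercise every exclusion and neutrality path and
  must never classify as damaging.
* QC fields: allele fraction Beta(20, 20) folded into the passing range,
  depth 12 + Poisson (mean 60), readPosRankSum standard normal folded above
  −1.7 and missing with probability 0.9 for indels (0.1 for SNVs).
  Dedicated `frac_fail_*` knobs inject calls failing exactly one rule each,
  and a configurable fraction of samples (default 10/192 ≈ 5.2%, the
  exclusion rate of the modelled design) falls below the coverage bar.
* Controls: per gene and tier, a Binomial(n_controls, rate) carrier count
  split multinomially across the catalog variants; denominator =
  n_controls.
* Randomness: one seed, three named `numpy` child streams (catalog, cases,
  controls) with documented draw order. The catalog stream is shared, so
  cases and controls draw from the same variant catalog for a given seed.

## Verification experiments and problem sizes

Problem sizes were chosen to give tight Monte-Carlo error at desk scale:

* **Fixture exactness** — the 31 packaged case variants reproduce their
  published tier labels with zero mismatches (11 Tier 1, 20 Tier 2).
* **Fisher regression** — all 66 published gene-level and pan-gene
  p-values are reproduced to three decimals from the printed counts;
  published `<0.001` entries compute below 0.001.
* **Oracle equivalence** — exhaustive agreement (absolute error < 1e-9)
  with exact integer enumeration over all 2×2 tables with grand total ≤ 60
  (~6.3 × 10⁵ tables).
* **Parameter recovery** — 200 replicate case cohorts (n = 122) at the
  study's per-gene Tier 1 rates; pooled pipeline-recovered rates fall
  inside a *simultaneous* binomial 95% band (Bonferroni z = 2.64 across
  the six genes). Per-gene 95% intervals are deliberately not used: with
  six genes the probability of at least one chance excursion is ≈ 26%
  even when the generator is exactly calibrated.
* **Type-I error** — at equal case/control carrier rates (0.1, n = 60 vs
  300, 1000 replicates) the end-to-end rejection rate at α = 0.05 matches
  the test's *exact achievable size* (computed by enumerating the two
  binomial carrier-count distributions, ≈ 0.037 under this design) within
  three standard errors and stays below nominal. Fisher's exact test is
  discrete and therefore conservative; its true size at small n sits
  strictly below 5%, so nominal-level agreement is asserted as size
  control, not as equality with 5%.
* **Power** — at carrier rates 12.3% (n = 122) vs 1.63% (n = 6192) the
  test rejects at α = 0.001 in > 80% of replicates, consistent with the
  strongly significant pan-gene contrast the design was built to detect.

## Known limitations

* The default gene panel ships the 17 genes observed in the packaged
  fixture plus a canonical extension; the original 175-gene panel is not
  published, so faithful reuse requires a user-supplied panel file.
* Variant identifiers degrade gracefully: `chrom:pos:ref:alt` when
  coordinates are known, otherwise a surrogate from gene / rsID / protein
  change (the packaged fixture has no published coordinates). No
  left-alignment or normalisation is performed.
* Control carrier estimation inherits the at-most-one-mutation-per-gene
  assumption and the pan-gene summation overestimate of the design it
  models.
* The classifier is a threshold rule set, not an ACMG-style evidence
  aggregation; it is only as good as the upstream annotations.
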