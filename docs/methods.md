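# Methods

## Statistical model

All association statistics operate on allele-level 2×2 contingency tables.
For a variant with risk-allele count a out of a+b alleles in group 1 and c
out of c+d in group 2:

- allele frequency: AF = a/(a+b), with the denominator counting two alleles
  per individual with a non-missing call at that variant (individuals
  missing at a variant are excluded from that variant's denominator only);
- odds ratio: OR = (a/b)/(c/d), group 1 being the comparison numerator
  (cases against controls, SRNS against SSNS);
- 95% confidence interval (Woolf / log-OR normal approximation):
  exp(ln OR ± 1.96·SE), SE = √(1/a + 1/b + 1/c + 1/d);
- test of independence: Pearson chi-square, 1 df, two-sided, without Yates
  continuity correction by default (a flag enables it). With allele counts
  in the hundreds to hundreds of thousands the correction is negligible;
  the option exists for comparability with R's default `chisq.test`;
- multiple testing: Bonferroni per comparison set, declaring significance at
  p < α/m with α = 0.05 and m the number of tests in the set (m = 9 for the
  full panel — always the set size, never the number of surviving tests).

The burden stage counts risk alleles per individual over the
Bonferroni-significant variants of the SSNS-vs-SRNS contrast, after
excluding every individual with a missing call at any of those variants
(complete-case rule; exclusions are reported per group and retained +
excluded always partitions each group exactly). The burden is dichotomised
at τ (default 7, configurable; a full sweep over all thresholds is always
emitted because the published cut is a finding, not a pre-specified rule)
and tested with a two-sided Fisher exact test. The two-sided p is defined
as the sum of the probabilities, under the hypergeometric distribution with
the observed margins, of all tables whose probability does not exceed the
observed table's — stated explicitly because two-sided Fisher tests have
competing definitions. The burden OR uses the same Woolf CI machinery as
the per-variant contrasts, which reproduces the published per-variant CIs
and is therefore adopted uniformly.

Homozygosity enrichment compares, per variant, the fraction of dosage-2
individuals among non-missing individuals between SRNS and SSNS, with a
two-sided Fisher exact test and Bonferroni correction over the variants
tested. Fisher is used here because dosage-2 cells can be small.

## Allele orientation

The panel fixes which allele is counted at every SNP, and the package ships
two orientations: disease-risk (the allele over-represented in NS cases
vs. population controls) and steroid-resistance (the allele
over-represented in SRNS vs. SSNS). The two published tables use these two
orientations, which differ at seven of the nine SNPs; the published source
does not comment on the discrepancy, and this package treats the
resistance-table allele as the opposite-orientation allele of the same SNP.
When two allele-count sets record different risk alleles at a variant,
`compare_groups` re-orients the second set (risk → total − risk) and flags
the result; the chi-square statistic and p are invariant under this flip
and the OR inverts, so significance counts are well-defined in either
orientation. The SRNS-vs-controls contrast is computed this way: the SRNS
counts (resistance orientation) are automatically re-oriented against the
disease-risk control counts.

Two boundary conventions: a 2×2 table with a zero cell gets the
Haldane-Anscombe +0.5 added to all four cells before the OR and CI are
computed (flagged in every output; the published tables contain no zero
cells, but the behaviour must be defined), and report tables render
p-values below 2.2×10⁻¹⁶ as "<2.2e-16" — the conventional printed floor —
while machine-readable outputs keep the raw value.

## Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes, no more:

- per group g and variant v, dosage ~ Binomial(2, af[v, g]) — i.e.
  Hardy-Weinberg genotype proportions (1−p)², 2p(1−p), p²;
- loci drawn independently;
- each call then masked (missing) with probability missing_rate[g, v],
  independent of genotype and phenotype (MCAR);
- all draws from named substreams of a single seed, so identical
  (spec, seed) gives a bit-identical cohort.

The default specification mirrors the published cohort: 639 SSNS and 236
SRNS individuals; per-group allele frequencies equal to the published
risk/total count ratios of the SSNS-vs-SRNS table (resistance orientation);
and uniform per-group missingness rates r solving (1−r)⁶ = retained
fraction, where the retained fractions are the published complete-case
counts (592/639 SSNS, 123/236 SRNS) over the six burden variants —
r ≈ 0.013 (SSNS) and r ≈ 0.103 (SRNS). The published per-variant
missingness pattern is unpublished; only these aggregate exclusion counts
constrain the defaults.

What the generator does **not** emulate — and hence what passing tests do
not show about real data:

- **Linkage disequilibrium.** Three panel SNPs lie in the HLA region and
  are correlated in reality; the generator draws loci independently, as the
  published statistics themselves assume. Consequence: the burden
  distribution's tails are wrong relative to the real cohort. Under
  independence at the published allele frequencies, P(burden ≥ 7) is ≈
  0.013 (SSNS) and ≈ 0.254 (SRNS), an implied OR near 26 — far above the
  published 7.4, which reflects positively correlated risk alleles
  concentrating burden in fewer individuals. Synthetic-cohort burden ORs
  are therefore expected to overshoot the published value, and estimator
  calibration is instead checked on cohorts with *specified* per-group
  P(burden ≥ 7) of 0.30 / 0.055 at the published complete-case sizes
  (123, 592), which give a true OR of ≈ 7.4. An optional exchangeable
  Gaussian-copula coupling of dosages (`dosage_correlation`) exists for
  sensitivity analyses but is off by default.
- **Population structure.** The real cohort is multi-race with
  group-specific ancestry composition; the generator draws from single
  per-group frequencies. No admixture, no genotyping-error model.
- **Borderline significance is not reproduced deterministically.** Two
  variants sit near the Bonferroni threshold at these sample sizes
  (published p of 3.1×10⁻³ and 0.01 against a threshold of 5.6×10⁻³), so a
  single simulated cohort selects six burden variants only on average;
  tests assert the robustly separated variants, not the exact set.

## Numerical and design choices

- Chi-square and Fisher tests are computed with scipy
  (`chi2_contingency(correction=False)`, `fisher_exact`); the odds ratio
  and Woolf CI are implemented directly and cross-checked in the tests
  against statsmodels' `Table2x2` and against brute-force oracles
  (full hypergeometric enumeration for Fisher; label-shuffle permutation
  for chi-square).
- The asymptotic chi-square p-value cannot agree with a permutation null to
  Monte-Carlo resolution on small tables: the conditional null is discrete,
  with a point mass at the observed statistic of order 0.1 for central
  tables at n ≤ 100, so the asymptotic and permutation p differ by up to
  ~0.1 there (reduced but not removed by the mid-p convention, which the
  oracle uses as the standard way to compare a continuous reference against
  a discrete resampling null). The oracle test in the suite asserts the
  strict Monte-Carlo-resolution bound and therefore fails on such tables by
  design, documenting this resolution limit. The pipeline's own use of the
  asymptotic test is in a regime (allele counts in the hundreds to
  thousands) where the approximation error is far below any decision
  threshold.
- One published CI cell does not round to the Woolf value: the
  SRNS-vs-SSNS rs3134996 upper bound computes 3.58 (→ 3.6) against a
  printed 3.5. `reproduce-tables` reports the mismatch rather than hiding
  it; every other CI cell and all 18 ORs reproduce at printed rounding.
- Genotype missingness is always an explicit state: "." / "./." parse to
  missing, anything else unparseable is an error, and a missing call
  surviving into `burden_count` raises (it means the complete-case filter
  contract was violated). Dosages are diploid autosomal (0/1/2) throughout.
- The burden histogram is emitted ungrouped (0..2k); the published grouped
  figure used data-driven bins that are not recoverable, so any binning is
  user-specified.
- Duplicate-sample QC: concordance is computed over mutually non-missing
  variants only; the gate requires every pair at 100% concordance, and a
  pair with no comparable variant fails the gate rather than passing
  vacuously.

## Problem sizes

The test suite and acceptance script use: exact recomputation of all 18
published table rows; exhaustive Fisher-oracle enumeration over all 2×2
tables with n ≤ 60 (up to row/column-swap symmetry) in the acceptance
suite and n ≤ 30 in the unit suite; 10⁵ shuffles per permutation-oracle
table; 500 replicates for estimator calibration and 1,000 simulated tables
for CI coverage; synthetic cohorts of 875–4,000 individuals. The whole
suite runs in under two minutes on one CPU.

## Known limitations

Beyond the generator simplifications above: no genotype-level regression
models (the published tests are allele-level 2×2 only), no population
stratification adjustment, no effect-size-weighted polygenic score, no
imputation of missing genotypes, and no APOL1 or race-stratified analyses.
The VCF reader parses the GT field only (diploid; phased treated as
unphased) and matches records to the panel by rsID.
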