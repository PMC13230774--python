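# Methods

## Variant categorisation

Categories are assigned in severity order — hcLOF, then missC, then
synonymous, then none — so every variant belongs to exactly one.
Score thresholds are **inclusive** (CADD ≥ 24, REVEL ≥ 0.5, MVP ≥ 0.8),
matching common usage of the CADD cutoff; a missing score counts as not
passing, which is conservative: an unscored missense variant can never
be promoted into missC. Rarity requires *every reporting* allele
frequency source to lie strictly below `rare_maf` (default 10⁻³); a
source that does not report the variant imposes no constraint, because
absence of a frequency estimate is not evidence of rarity or of
commonness. Multi-allelic sites are split into biallelic records before
any filtering, so each alternate allele carries its own frequencies and
category.

The threshold-selection machinery reproduces how the score ensemble is
chosen: rank-based AUC (midrank ties) within LOF-constrained
(LOEUF < 0.35) and non-constrained gene strata, a score qualifying when
both AUCs exceed 0.9, and a working threshold at the maximum of
Youden's J on the pooled labelled set. Ties on J resolve to the
smallest qualifying threshold, making the report deterministic. The MPC
score is carried through the selection machinery as an extra column but
is never used by the classifier, so the selection step can reject it on
data rather than by fiat.

## Gene-level burden

The Fisher test is **one-sided toward case enrichment**: the discovery
direction is excess carriers in cases, and a gene with zero case
carriers is uninformative (p = 1) rather than protective. The p-value
is the exact hypergeometric upper tail of the 2×2 carrier table.
Carriers are counted per individual, never per allele, and hemizygous
male X genotypes count as carriers — otherwise X-linked genes would be
untestable in males. The minimal-P tie between categories resolves to
hcLOF (the more severe class), again for determinism.

Multiple testing uses a fixed family of n = n_genes_tested × 2
categories (study scale: 2 × 16,351 = 32,702). The BH step-up ranks
genes **within each case stratum's gene list** but multiplies by the
full n; genes whose categories have no qualifying variants in either
arm contribute p = 1 and are excluded from the rank list. This scheme
reproduces every arithmetically reproducible adjusted value in the
bundled published top-gene table, including the tie-block and step-up
behaviours. Four of the 42 published adjusted cells differ in the last
printed digit when recomputed from the 3-significant-digit minimal P
values; they are flagged in the bundled table as rounding artefacts of
the published source precision.

The recessive analysis treats "protein-altering" as the union of the
two discovery categories (hcLOF, missC). Compound heterozygosity is
approximated by ≥ 2 distinct qualifying heterozygous variants in one
gene without phase information; this over-counts cis pairs by design
and is documented as an upper bound on recessive carriers.

## Gene-set burden

The per-sample MAC sums dosages over QC-passing rare qualifying
genotypes within the set's genes. The logistic fit is plain
maximum-likelihood (Newton/IRLS, |Δ| < 10⁻⁸, ≤ 100 iterations) with
five ancestry PCs and sex as covariates; an independent hand-written
Newton solver in the test suite verifies the coefficient to 10⁻⁶.
Unknown sex is imputed to the cohort majority rather than dropping
samples, which would silently change stratum sizes. Degenerate
exposures (constant MAC) and quasi-separation are *flagged* on the
result rather than patched with penalised likelihood, because the
reference analysis is unpenalised logistic regression; rank-deficient
covariate columns are dropped with a warning.

Constraint deciles cut the LOEUF- (or MOEUF-) ranked gene list into ten
contiguous near-equal bins, ties broken by gene id; bin 1 is the most
constrained. Per-category Bonferroni families are #sets × #strata —
45 for the 15 DEG clusters × 3 strata, 30 for the ten bins, by the same
construction. The pooled aCHD stratum is the union of sCHD and nsCHD
cases; an enrichment planted only in sCHD therefore *also* elevates the
aCHD estimate, attenuated by the nsCHD dilution — end-to-end checks
treat a pooled-stratum flag as inherited signal, not as a false
positive.

## Calibration

λ_GC is the median of the χ²(1)-quantile-transformed p-values over the
null median (≈ 0.4549); λ₁₀₀₀ rescales it linearly to an equal-arm
1000/1000 study. QQ expected quantiles follow the −log₁₀((i − ½)/n)
convention.

A structural property worth stating: one-sided Fisher p-values on
sparse discrete carrier counts are *conservative* — the attainable
p-values are a discrete set whose null distribution is stochastically
larger than uniform, so on well-behaved null data λ_GC sits **below** 1
(≈ 0.85–0.95 at the simulated scales here) and approaches 1 only as
carrier counts grow. The calibration diagnostics are therefore designed
around the label-permutation null, which shares the discreteness: the
observed λ is compared against its own permutation distribution
(stratified permutation preserving the control/sCHD/nsCHD counts is the
default, as it matches the study design), and the MAF-stratified
synonymous check flags only the inflation direction. The number of
permutations defaults to 100 and is configurable; analyses here use 30
to stay light.

## The synthetic cohort generator

Defaults are the modelled study's conditions: 1,818 sCHD + 2,929 nsCHD
cases vs 52,881 controls, 19,923 protein-coding genes, rarity at
MAF < 10⁻³, the DP ≥ 10 / GQ ≥ 20 / AB > 0.2 QC regime, and the
study-preset planted odds ratios (2.27 / 1.52 for bin-1 hcLOF in
sCHD / nsCHD). Genes draw LOEUF/MOEUF from correlated log-normals; ~3 %
of genes are X-linked and male carriers there are hemizygous. Variants
carry score triplets consistent with their intended category,
multi-source AFs (a 10 % common-site mixture component sits above the
rarity threshold), and genotypes carry DP ~ negative binomial
(mean 40), GQ ~ discretised Gaussian (60 ± 15) and het AB ~ Beta(20,
20), so a realistic small fraction of calls fails QC.

Carrier probabilities are planted at the **gene level**: a planted
(target, category, stratum, OR) shifts each targeted gene's per-sample
carrier probability by ln(OR) on the log-odds scale in that stratum's
cases — matching the carrier-based alternative the Fisher and MAC tests
are built for. Targets resolve to a gene id, a LOEUF decile (`bin_1` …
`bin_10`, computed from the generated LOEUF values), or a DEG cluster
label. Two cluster mechanisms exist: a cluster *target* gets a
dedicated enriched gene set, while `deg_overlap` makes a named cluster
share genes with the already-planted risk set. The overlap mechanism is
the one used in end-to-end checks, because a dedicated enriched cluster
necessarily scatters its genes across constraint bins and leaks signal
into the bin battery, whereas overlap keeps all enrichment inside the
planted decile — and it is also the more realistic picture (constrained
risk genes being differentially expressed in the relevant cell type).
Non-planted clusters are drawn from effect-free genes, so the cluster
battery is null-calibrated outside the planted combinations.

The per-gene baseline carrier rate is 10⁻³ for the protein-altering
categories. The synonymous category uses a separate baseline of 0.05:
rare synonymous variation is roughly an order of magnitude more
abundant per gene than qualifying hcLOF/missC sites, and this rate also
sets the granularity — hence the conservativeness — of the
negative-control null described above. PCs are independent of status by
default; `pc1_case_shift` provides a confounding mode to demonstrate
covariate adjustment.

What the generator does **not** emulate: linkage disequilibrium,
realistic site-frequency spectra beyond the rare/common mixture,
relatedness, batch or capture-platform effects, and phase. Passing
tests therefore demonstrate the statistical machinery under its own
assumptions, not robustness to the population structure and technical
artefacts that real cohorts carry — that is exactly what the
calibration diagnostics exist to monitor on real data.

## Expression profiling

Early-window means average RPKM over samples at 4–8 weeks post
conception (inclusive); percentile ranks use the midrank convention
100 × (rank − ½)/n, invariant under monotone transforms. Set
comparisons use the two-sided Wilcoxon rank-sum on percentiles — exact
null for combined n ≤ 20 without ties, normal approximation with
continuity correction otherwise — with Bonferroni over the tissues
tested.

## Problem sizes

Tests and the analysis drivers run scaled-down renditions of the study
conditions, chosen as the package's own working sizes: cohorts of a few
hundred to ~15,000 samples over 300–1,500 genes, a 25,000-sample design
for logistic parameter recovery (≈ 5,000 cases / 20,000 controls, 200
replicates; 1,000 replicates for the type-I error rate so the
Monte-Carlo error is small against the ±2-percentage-point band), and
30 label permutations for calibration. The multiple-testing arithmetic
itself is scale-free and runs at the full published family size.

## Known limitations

- Published per-gene raw P values cannot be regenerated from the
  printed carrier counts plus headline cohort sizes; back-calculation
  implies smaller post-QC stratum sizes that were not published. The
  pipeline therefore treats stratum sizes as data, and verification
  against the published table covers the multiple-testing arithmetic,
  which is exactly reproducible.
- The unphased compound-het proxy cannot distinguish cis from trans
  pairs.
- Quasi-separated logistic fits report flags, not estimates; downstream
  consumers must check the `converged` / `quasi_separated` columns.
- The VCF importer expects split-ready biallelic semantics for
  Number=A INFO fields; exotic annotation layouts need a field map.
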