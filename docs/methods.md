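# Methods

## The generative model behind the synthetic cohort

The generator emulates a two-way admixed population (African/European, as in
African Americans) under a **single-pulse admixture model**: the admixture
event happened `G` generations ago (default 12, matching the training depth
of the local-ancestry inference the analysis assumes), after which
recombination has laid ancestry breakpoints along each haplotype as a
Poisson process at rate `G` per Morgan. Each resulting segment is labelled
African independently with probability `α` (default 0.8; African Americans
are typically 75–80% African). Segments are exchangeable: no pedigree, no
drift, and no correlation between adjacent segment labels. This is exactly
the structure the attribution analysis assumes, and it is sufficient for
validating attribution, ancestry-fraction recovery and the
frequency-mixture arithmetic; it is *not* a coalescent simulation.

The genetic map defaults to a uniform 1 cM/Mb over 22 autosomes with
approximate GRCh38 physical lengths; any `(chrom, bp, Morgans)` map can be
supplied, and analyses can be scoped to a chromosome subset (real local
ancestry painting often covers only some chromosomes).

**Alleles.** Each alternate allele copy is drawn per haplotype conditional
on the local ancestry at its position: `Bernoulli(f_afr)` on African
tracts, `Bernoulli(f_eur)` on European tracts, independently given the
tracts. Consequently the expected African share of observed copies is
`α·f_afr / (α·f_afr + (1−α)·f_eur)`, and a variant absent from the African
background (`f_afr = 0`) appears on European tracts only — the ground-truth
pattern the attribution module must recover exactly. There is no linkage
disequilibrium beyond this shared-tract structure.

**Phenotypes.** Disease status is logistic and additive in log-odds:
`logit P(case) = b0 + Σ_v g_v ln(OR_v) (+ optional PRS term)`, with the
intercept `b0` solved numerically (Brent's method on the pool's empirical
score distribution) so the marginal prevalence equals `K` (default 0.01).
The source analysis never states a generative disease model; the logistic
form is the natural inverse of its odds-ratio-based arithmetic. Cases and
controls are then ascertained to quota from the simulated pool; an
infeasible quota (pool too small at prevalence `K`) is an error rather than
a silent shortfall. Haplotype phase and tract labels are known by
construction — there is no phasing-error or ancestry-call-error model, so
passing recovery tests demonstrates correctness of the estimators, not
robustness to inference noise in real data.

## Burden statistics

**Variance explained** is the liability-scale `2p(1−p)(ln OR)²`, reported
×100. It is invariant under `OR → 1/OR` and maximal in `p` at 0.5.

**Excess cases per 100,000** fixes `N = 100,000` people at prevalence `K`
and builds a carrier-by-status 2×2 table: expected heterozygotes
`H = 2p(1−p)N`; carrier controls `B = H(1−K)` and the
homozygous-reference control pool `D = (1−p)²N − (NK − HK)` held at their
null expectations; the carrier-case count that produces a target odds
ratio is `x(OR) = OR·B·NK / (D + OR·B)`. The reported excess is
`x(OR) − x(1)`.

Two details deserve comment. First, the *baseline* is `x(1)` — the carrier
case count that makes the same table exactly multiplicative-null — rather
than the raw null expectation `HK`. On the pooled-carrier path the two
coincide identically; on the heterozygote path they differ by a term of
order `p²` (the disregarded alternate-allele homozygotes), and only the
`x(1)` baseline makes `excess(p, OR=1) = 0` exact and the sign of the
excess match the sign of `OR − 1` for all `p`. Second, the solve is
continuous and rounding (half away from zero) happens at the reporting
layer only; integer-stepped arithmetic on the same cells can differ by up
to one case.

Cells of the packaged summary table that cannot be reproduced from their
own printed 2-d.p. frequency and odds ratio under this procedure (they were
evidently computed from unrounded cohort frequencies) are *flagged* by
`burden.check_printed_consistency`, not matched: the implementation reports
its own values.

**Rarity classes** follow the European-frequency conventions with the
boundary handling implied by the printed inequalities: ultra-rare
`MAF ≤ 0.001`, very rare `0.001 < MAF ≤ 0.01`, rare `0.01 < MAF < 0.05`,
common `MAF ≥ 0.05`.

**Association** uses Fisher's exact test on allele-level 2×2 tables
(carrier-level for set aggregation), without covariate adjustment — at
rare-variant frequencies in modest cohorts there is no power to support
covariate modelling. The two-sided p sums hypergeometric probabilities no
larger than the observed table's; it is computed with exact integer
numerators over the common denominator `C(n, a+c)`, which resolves
probability ties exactly and is fast enough to sweep every small table.
Odds-ratio estimates are suppressed (flagged) when the cohort MAF is below
0.001, where the cross-product estimator is unstable.

**Allele orientation.** All statistics are computed for the designated
ascertained allele, which is held fixed across cohorts and never re-minored
per cohort — re-minoring silently flips effect directions whenever an
allele is minor in one ancestry and major in another. The reader warns when
an ascertained allele exceeds frequency 0.5 in any cohort column.

**EP filter.** Variants with evolutionary-probability score strictly below
0.0022 (the empirically pathogenic-enriched range) are retained.

## Ancestry attribution and regressions

A copy at 1-based position `p` belongs to the tract containing `p − 1`
under half-open 0-based intervals; a copy exactly on a boundary therefore
belongs to the later-starting tract — deterministic, no tie. Attribution is
exact given tracts, so on simulator output it must (and does) match the
truth tables copy-for-copy, and copy counts are conserved exactly. A
variant with no observed copies has an undefined (NA) African proportion,
not zero. Disease-group pooling counts a variant's copies once per group it
maps to, since group memberships overlap.

The ancestry-vs-burden relationship is summarized by ordinary least squares
of the per-individual European fraction on the number of target variants
carried, with the Pearson correlation and its two-sided t-distribution p —
the source analysis names no regression form, and with a single predictor
OLS + Pearson is the minimal choice. PRS-vs-ancestry uses Pearson
correlation per weight set and stratum, no covariates.

## Nucleotide diversity

Per-site π for a biallelic site on `n` observed chromosomes is
`2·c_ref·c_alt / (n(n−1))`. The gene-level statistic is defined here —
the source describes an "adjusted" metric without writing the formula — as
the sum of per-site π over polymorphic CDS sites divided by the total CDS
length, with unobserved positions contributing zero. The number of observed
CDS sites is carried in the result, and a coverage-adjusted column
(π-sum per *observed* site) is reported alongside so cohorts with unequal
site presence can be compared; neither value is silently substituted for
the other. Ancestry conditioning restricts a stratum to individuals whose
both haplotypes are a single ancestry across the gene span, and seeded
down-sampling (default 10 replicates) matches cohort sizes before
comparison.

## Numerical and design choices

* All randomness flows from a single integer seed per run; identical
  config + seed gives byte-identical output files (hashes recorded in the
  run manifest).
* Breakpoint positions are drawn uniformly on the physical chromosome
  (exact under a uniform cM/Mb map) and deduplicated; segment labels are
  i.i.d., so adjacent same-label segments are kept rather than merged.
* The logistic intercept is solved to `xtol = 1e-12`; with all odds ratios
  at 1 the case probability is exactly `K`.
* Table output rounds MAF/OR/%VE to 2 decimals and excess cases to
  integers (half away from zero), matching the print precision of the
  source tables; all internal arithmetic is unrounded.
* VCF round-trips carry variant metadata (gene, background frequencies,
  assumed OR, direction) in INFO fields written as strings at full float
  precision, because the VCF `Float` INFO type is 32-bit in common parsers.
* Readers reject malformed input (unphased genotypes, non-biallelic
  records, overlapping or gapped tracts, out-of-range frequencies, unknown
  labels) with the file and record named; nothing is coerced.

## Problem sizes used in the test suite

Simulation-recovery checks run at the study's scale where that is cheap
(3,400 individuals, ten painted chromosomes, `α = 0.8`, `G = 12`) and at
reduced or specialized scales elsewhere: odds-ratio consistency uses 10⁶
haplotype draws at a single locus, mixture-proportion checks use 10⁵
haplotypes on a short map, and pipeline determinism uses a few-hundred
sample demo on two chromosomes. Tolerances for stochastic checks are
derived from binomial/regression sampling error (typically 4 standard
errors), not tuned constants.

## Limitations

* No coalescent realism: allele frequencies are fixed parameters (no
  drift), and there is no background LD, so the generator cannot probe
  LD-dependent artefacts of attribution.
* No phasing-error or local-ancestry-error model; real painted cohorts
  overestimate breakpoint counts and misassign short tracts.
* `α` is a global constant per simulation; per-individual ancestry
  variation beyond the tract process itself (e.g. Beta-distributed
  admixture proportions) is not modelled.
* The X chromosome and multi-allelic sites are out of scope.
* The published cohort-genotype results that require the restricted WGS
  data (specific correlation magnitudes, the 17/300 African-haplotype
  count) are reproduced only as qualitative patterns on simulation.
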