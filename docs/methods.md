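# Methods

## The adjusted haplotype conditional-entropy score

**Windows.** Per-site entropy is the biallelic Shannon entropy in nats,
computed within one population over all of that population's chromosomes.
The window around a focal marker extends outward on each side until the
cumulative flank entropy (focal site excluded) first reaches the threshold
(default 10 nats per flank). The expansion is greedy and per-side, which is
also provably minimal: sites are added in a fixed order, so the first
prefix reaching the budget is the shortest one. Windows are site-index
ranges, not base-pair ranges. If a chromosome end arrives before the budget
is met, the flank is truncated and the truncation flag is propagated into
the score record rather than dropping the marker. Monomorphic sites inside
a window contribute nothing to the budget and are kept as (constant)
haplotype positions.

**Entropies.** `H*` is the plug-in entropy of the distinct flanking
haplotype strings; `H'` is the same entropy restricted to chromosomes
carrying the minor allele at the focal site. No bias correction is applied
— the plug-in estimator is the definition of the statistic. The minor
allele is decided per population (frequency within that population, a tie
at exactly 0.5 resolved toward the ALT allele); a `minor_scope="global"`
option pools all populations for the minor/major call instead, since both
conventions are defensible.

**Inclusion rule.** A population contributes to a marker's score only when
it has more than 5 major-allele chromosomes and at least one minor-allele
carrier (without a carrier the conditional entropy is undefined). The
bound-on-major-count form is implemented literally; `inclusion="minor"`
applies the same bound to the minor-allele count instead, for users who
read the condition as a misprint. Both modes are tested; the literal form
is the default.

**Calibration.** The adjustment `(α_p, β_Mp, β_mp)` is obtained by ordinary
least squares of `H* - H'` on `{1, ln N_Mp, ln N_mp}` within each
population. OLS with an intercept is the unique linear adjustment in these
two regressors whose residuals average exactly zero per population, which
is the property the calibration is defined by. At least 3 usable markers
per population are required, and a rank-deficient design (e.g. constant
minor-allele count) is a hard error naming the population. When no
calibration table is supplied, scoring is two-pass: components for all
focal markers first, then the calibration fitted on that same set. The
aggregated score negates the calibrated sum, so swept markers score
negative; the text description of "high score = swept" corresponds to the
`flip_sign=True` output option, which is off by default so that the formula
is implemented exactly as written.

## Missing data and panel conventions

Only biallelic SNPs are loaded; indels, multiallelic records and records at
duplicated positions are dropped with counts logged. A missing or unphased
call masks its site within the affected population only (entropy over
partially observed haplotypes is undefined), so site sets may differ
between populations; a population in which the focal site itself is masked
simply does not contribute to that marker. Coordinates are 1-based VCF
positions throughout.

## Predictors, annotation and strata

External per-population selection statistics are reduced to one value per
SNP by summing natural logs across populations (p-values are floored at
1e-300 before the log; frequency-type values of zero are skipped, since a
monomorphic population carries no frequency information; all-missing rows
propagate NaN and are excluded from fits using that predictor). Natural
logs keep the convention uniform with the entropies; any other base only
rescales coefficients.

Raw gene-model labels collapse to exonic > UTR > intronic > flanking with
the highest-priority category winning; flanking means within 1 kb (the
annotation tool's default) of the most distal promoter or terminator, and
anything further from every gene is intergenic. Every SNP gets exactly one
stratum: its gene, or the enclosing intergenic interval (each interval a
distinct stratum). Overlapping gene spans are resolved to the nearest
transcription start, ties broken by lexicographic gene symbol — the source
analyses are silent here, so determinism was the deciding criterion.

GO singletization picks, per gene, the membership whose universe size is
closest to 125 genes (ties to the smaller category, then lexicographic ID);
categories retaining ≤ 50 genes after this assignment are merged into
OTHER, applied after the closest-to-125 choice, as are genes without any
membership and all intergenic strata. Strata with zero flagged SNPs are
dropped per dataset; all-case strata are dropped too, because their
conditional-likelihood contribution is constant (the published filter only
mentions the zero-case side; the all-case side is the same degeneracy
mirrored).

## Conditional logistic regression

The likelihood is the exact conditional likelihood — per stratum, the case
set's probability among all subsets of the same size. One-case strata (the
design the simulator produces by default) use a vectorised per-stratum
softmax; multi-case strata use the standard one-pass recursion over the
subset-sum polynomials, with analytic gradient and observed information
from the same recursion. No Breslow-style approximation is used at any
stratum size. Fitting is Newton–Raphson with step-halving, relative
log-likelihood tolerance 1e-9, 50 iterations maximum. Separation is
reported (never silently) when a coefficient escapes ±50 with the
likelihood still rising, or when the conditional likelihood becomes
numerically 1 (every case set perfectly predicted); partial separation that
does neither within the iteration budget surfaces as non-convergence.
Standard errors come from the inverse observed information; "z" is the Wald
ratio β/σ with no degrees-of-freedom correction.

Interactions of a numeric predictor with a categorical (GO or group) expand
to one slope per observed level; since the stratum fixes the level, these
are within-level slopes and the level's main effect is absorbed by the
stratum. The reference-level slope is dropped only when the numeric main
effect is also in the model. Categorical main effects are dummy-coded with
intronic (location) / OTHER (GO) / neither (group) as reference when
present — any other choice only relabels contrasts. Columns constant within
every stratum are dropped with a warning; they are not identifiable
conditionally (this is exactly how an overly smooth predictor breaks these
models). The group-contrast test is a Wald contrast
`z = (β₁ - β₂)/√(σ₁² + σ₂²)` with a two-tailed normal p, treating the two
slope estimates as independent.

## Meta-analysis and the permutation null

Per dataset and GO category, the fitted score slope is shrunk one standard
error toward zero (clamped at zero) and summed across datasets; a category
absent from a dataset, or a dataset whose fit fails to converge,
contributes zero (logged). The null is built by permuting the single
gene→GO assignment (shared across datasets) among non-OTHER genes —
category sizes are preserved exactly and OTHER is never touched — refitting
every dataset per permutation (default 100, seeded), and pooling all
permutation × GO sums into one empirical central 90% interval. Per-GO
intervals are available via `null_interval` on per-GO pools for sensitivity
analysis, but the pooled interval is the primary method. Classification is
strict: sums equal to an endpoint are inside (conservative). An exclusion
list (by default the catch-all cellular-metabolic-process category) removes
entries from the group lists without hiding their classification. Group 1
is the below-interval set and Group 2 the above-interval set, following the
results-table convention.

## The synthetic-data generator

Each region draws `pool_size` founder haplotypes as i.i.d. 0/1 strings;
every chromosome copies one founder, with founder frequencies drawn per
population from a symmetric Dirichlet. This is deliberately coalescent-free
— it produces the within-window linkage structure the entropy contrast
needs while staying cheap and fully seeded; an external simulator can be
substituted through the VCF interface. Focal markers are inserted as extra
columns: neutral markers scatter the minor allele independently of the
founders; swept markers place fraction `sweep_purity` of carriers on a
single founder, choosing a founder large enough to host them (and shrinking
the carrier count when none is — a sweeping variant cannot outnumber its
background). Regions live on separate contigs, so windows never cross
regions and a purity-1.0 sweep forces `H' = 0` exactly when each region
carries one focal marker; with several markers per region, neighbouring
focal columns add carrier heterogeneity, which is realistic but weakens
that exact identity.

Defaults — 3 populations × 50 diploid samples (about a hundred chromosomes
per population, the scale of a reference-panel population), 120 sites and
8 markers per region, purity 0.9, one case per ~10 SNPs per stratum — are
chosen for statistical health of the conditional fits, not to mimic any
particular cohort. What the generator does **not** emulate: recombination
gradients, mutation-rate heterogeneity, realistic demography, linkage
between regions, and ascertainment of the focal-marker list. Passing tests
therefore demonstrate correctness of the statistics and calibration of the
inference under exchangeable, well-specified conditions — not performance
on real cohort data.

Study tables are sampled from the exact conditional model: within each
stratum the case set is drawn with probability proportional to
`exp(Σ η)` over subsets of the planted size, so slope-recovery tests face
precisely the likelihood being maximised. Multi-case sampling enumerates
subsets and is limited to small strata.

## Problem sizes used in checks

Entropy and likelihood oracles run on exhaustive small configurations
(strata up to n = 10, k = 3; haplotype tables up to 16 × 8). Calibration
checks use 10,000 markers × 14 populations. Regression calibration uses 500
strata × 10 SNPs over 100 replicates; sweep contrasts 200–300 single-marker
regions per arm; permutation-null coverage 20 replicates of 2 datasets ×
150 strata with 100 permutations; the planted-GO detection demonstration 7
datasets × 300 strata. These sizes give stable Monte-Carlo behaviour on a
single CPU; all are configurable.

## Known limitations

- The entropy estimator is plug-in; for very small minor-allele counts
  `H'` is strongly discrete (0 for singletons), which the calibration
  absorbs only on average.
- Firth-type penalisation for separation is not implemented; separated
  fits are flagged and excluded from meta-sums rather than regularised.
- The permutation null treats datasets as independent given the shared
  assignment; shared genes across real datasets would induce correlation
  the pooled interval ignores.
- The group-contrast test assumes independence of the two slope estimates,
  which is exact only when the groups share no strata.
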