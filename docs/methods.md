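# Methods

## Model and test

A disease-associated gene sample of size `n` and a functional gene set of
size `K` are treated as subsets of a single gene universe of size `N`.
Under the null hypothesis of independent membership the overlap count `X`
is hypergeometric with mean `E = K·n/N`; the one-sided exact
(Fisher) p-value of overrepresentation is the upper tail `P(X ≥ O)`,
evaluated through `scipy.stats.hypergeom.sf`, which computes in log space
and remains accurate for tails far below 1e−300.  The test suite verifies
the tail against an independent exact rational summation (integer binomial
coefficients) for every parameter combination with `N ≤ 60`.

All tests are one-sided by design: the scientific question is
overrepresentation only.  No odds ratios or FDR procedures are computed;
multiplicity is handled by the conservative Bonferroni factor
`min(1, m·p)` with `m` defaulting to the number of rows in the table.

Gene symbols are canonicalized (trimmed, uppercased) before any set
operation, and both samples and functional sets are restricted to the
universe before sizing, with dropped-symbol counts logged — silent set
shrinkage is the main practical failure mode of intersection analyses.
No alias or cross-identifier mapping is attempted; inputs are assumed to be
pre-harmonized symbol lists.

## Table conventions

Each row reports `K`, `n`, `E` (count and percentage `100·K/N`), `O` (count
and percentage `100·O/n`), the representation factor `RF = O/E`, a
confidence statement on the number of matches, nominal and corrected p, and
a star label.  Display rounding: counts to integers, percentages and RF to
one decimal, p-values to two significant figures; all computation is
unrounded and raw values are kept in machine-readable output columns.

**Confidence bound.**  The published analyses this package generalizes
attribute their match-count intervals to one-sided exact tests without a
formula.  `genesect` uses the one-sided exact binomial (Clopper–Pearson)
lower bound for the proportion `O/n` at level 0.95, scaled to counts and
rounded, with the upper bound fixed at `n`.  This is documented as an
approximation of intent, not a claim about the original computation; in the
reference table it reproduces 22 of 23 printed lower bounds within ±1 (19
exactly).

**p-value floor.**  Exact-test software customarily prints no value smaller
than 2.2E−16.  `format_p` renders any p below 2.22e−16 as the floor string
`2.2E-16` and flags it; the corrected display value is the family size times
the *floored* nominal value (matching the convention of the reference
table), while raw nominal and corrected values are preserved unfloored.

**Stars.**  Association tables use `*` ≤ 1e−2, `**` ≤ 1e−3, `***` ≤ 1e−6 on
the corrected p (significance level 0.01 after correction); directional
expression tables use `*` ≤ 0.05, `**` ≤ 0.01.  Thresholds are configurable
per table.

**Reference-table reproduction.**  `reproduce_table1` recomputes every
derived column from the printed per-row inputs (K, n = 345, O, nominal p)
with universe size 21,000 and family size 23.  The universe size is a
reconstruction: it is not printed in the source but is recovered from the
expected-percentage column (`E% = 100·K/N` gives N ≈ 21,000 across rows)
and is configurable.  The printed nominal p-values are treated as inputs to
the corrected column because they are not exactly recomputable from the
printed counts at any single universe size; recomputed tails at N = 21,000
agree with the printed values to well within an order of magnitude on every
row, and exactly for most (the fixture run exposes both).

## Genome-resampling null

`resample_null` draws M samples of `n` distinct genes uniformly (by gene
label, no covariate matching) without replacement from the explicit
universe and records each overlap with the functional set.  The empirical
p-value uses add-one smoothing, `(1 + #{overlap ≥ O}) / (M + 1)`, so it is
never zero and is bounded below by `1/(M+1)`.  Uniform subset draws are
implemented as the bottom-`n` order statistics of i.i.d. uniform keys,
which vectorizes over chunks of iterations; results are bit-reproducible
from the seed.  `compare_to_analytic` calls the two routes concordant when
they differ by less than four binomial Monte-Carlo standard errors, or when
both lie below the `1/M` resolution of the empirical estimate.

## Synthetic data generator

The generator emulates the shape of the real analysis — a universe of
~21,000 symbols, functional sets of a few hundred to a few thousand genes
with controlled pairwise overlaps, samples of ~345 genes — while making no
attempt at realistic gene nomenclature, genomic structure, linkage, or
expression levels.  Passing tests on synthetic data therefore validate the
statistical machinery (calibration, power, parameter recovery), not the
biological curation of any real gene database.

*Set construction.*  Pairwise overlap targets are honored exactly: shared
cores are drawn first (from each constrained partner minus the other
constrained sets, so picks cannot disturb one another), then remainders are
filled disjointly.  Unsatisfiable targets raise with the violated pair.

*Planted enrichment.*  The disease sample is drawn without replacement with
per-gene weight equal to the product of ρ over the planted sets containing
the gene (a simple, documented composition rule; weight 1 elsewhere).
Sequential renormalized weighted draws are realized as an exponential race
(keys `Exp(1)/w`, `n` smallest win), which is exact and vectorized.  ρ = 1
recovers the uniform null; ρ = 0 excludes a set.  `rho_for_target_rf`
calibrates ρ to a target expected representation factor through the
limiting inclusion odds `K·ρ/(K·ρ + N − K) = RF·K/N`, exact as `n/N → 0`;
at the default n/N ≈ 1.6% the residual depletion bias in recovered RF is
about 1.5%, well inside the validation band.

*Reference fixture.*  `table1_fixture` assembles the universe from 23
disjoint membership atoms over the base categories whose sizes were derived
by inclusion–exclusion so that every base-set size, every derived-set size
(unions, interactions, exclusions) and every sample overlap equals the
published value exactly; the seed only shuffles which synthetic symbols land
in which atom.  This lets the whole pipeline be validated end to end from
raw gene-list files.

*Operating characteristics.*  `estimate_error_rates` reruns the pipeline per
replicate: type-I error with all ρ forced to 1, power with the configured ρ.
Validation sizes used by the shipped tests: 1,000 replicates for error rates
(binomial SE ≈ 0.7% at α = 0.05), 500 replicates for RF recovery, 20
configurations × 10⁵ iterations for resampling/analytic agreement at
N = 2,000 — sizes chosen to keep Monte-Carlo error a small fraction of the
tolerances being checked.

## Known limitations

- The confidence-bound method and the resampling scheme are documented
  reconstructions of intent (uniform, unstratified sampling; exact binomial
  bound); the original supplementary procedures may differ in detail.
- A size-only universe supports expectations and tests but not membership
  queries, so restriction and resampling require an explicit universe.
- Weighted-draw calibration is asymptotic in `n/N`; for samples that are a
  large fraction of the universe, planted RF will undershoot the target.
- The postmortem stage consumes published differential-expression lists; it
  performs no expression processing or differential calling of its own.
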