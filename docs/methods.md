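# Methods

## The analysis model

The pipeline targets the regime of a very small case-control exome cohort
(tens of samples per group) where single-variant association is hopeless and
even single-gene tests cannot reach exome-wide significance. Signal is sought
in aggregate: per gene (collapsing), per curated gene list (burden), and per
annotated gene set (over-representation). Three statistical primitives carry
the whole analysis; all are exact small-sample tests.

### Carrier collapsing and the exact Fisher test

Each subject is coded per gene as carrier (≥1 qualifying variant allele) or
non-carrier; the count of qualifying variants beyond the first is discarded
by design, which makes the statistic robust to per-sample variant-count
differences (a common capture/coverage artifact). Missing genotypes are
counted as non-carrier and logged — a conservative choice that can only
dilute, never inflate, carrier counts.

For a table (a = cases with, b = cases without, c, d likewise for controls),
the two-sided p-value follows the minimum-likelihood rule: conditioning on
both margins, a ~ Hypergeometric, and all tables with point probability ≤
that of the observed one (to a 1 + 1e-7 relative tolerance) contribute to p.
This matches the default two-sided convention of `fisher.test` in R. The
choice is observable in the data: a control-enriched table such as 0/35 vs
7/31 has p = 0.0119 under this rule, while a case-directional one-sided test
would return ~1.

Genes with zero carriers in both groups carry no information and are not
tested, but they remain in the reported universe of genes with ≥1 qualifying
variant, which is the correct denominator for the burden test: a gene whose
variants exist but fall only in QC-failed samples was still testable in
principle.

No multiple-testing correction is applied inside the collapsing analysis:
its role here is to rank genes and supply a nominal hit set (p < 0.05,
case-enriched) to the burden test, not to declare exome-wide discoveries. A
Bonferroni column over the tested genes is emitted for reference.

### Curated-list burden test

With N universe genes, K of them on the curated list (after intersecting the
list with the universe — genes that could never have been hits must not count
in K), n nominal hits and k curated hits, the reported value is the inclusive
upper tail P(X ≥ k) for X ~ Hypergeometric(N, K, n), assembled by
log-sum-exp over the upper support. The inclusive tail is the standard
over-representation convention (the observed overlap is evidence, not
background). For the published configuration of the original cohort
(N = 7496, K = 25, n = 34, k = 2) this evaluates to 5.612 × 10⁻³ — exact
rational enumeration and R's `phyper` agree to full precision — whereas the
original report prints 5.86 × 10⁻³; that printed value corresponds to no
parameterization near the stated one (it would require a universe of ≈7,330
genes) and is treated as a reporting discrepancy, not a target to emulate.

### Over-representation and exclusivity

Each gene set is scored with the same inclusive hypergeometric upper tail
against an explicit universe (default: the analyzable genes; an
"annotation" mode uses the union of set members instead, mirroring services
that supply their own background). Benjamini–Hochberg step-up adjustment is
applied independently within each set category, so sparse categories are not
punished for dense ones. BH here is the plain step-up: monotone along the
sorted order and pointwise ≥ nominal; note it is *not* idempotent
(BH([0.25, 1]) = [0.5, 1] but BH([0.5, 1]) = [1, 1]) — a property sometimes
misstated of the procedure.

A term is *exclusively* enriched when significant in the case query but in
neither the control query nor the case-synonymous query. The synonymous
stream applies the strict tier's frequency/deleteriousness rules to
synonymous variants: genes selected by it share every technical bias of the
case list (coverage, capture, population) but none of the presumed biology,
making it the natural negative control.

## Coverage harmonization

Thresholds (all configurable, defaults in `CoverageThresholds`):

| rule | default | convention |
|---|---|---|
| gene mean depth | > 50× | strict, per the inclusion flowchart wording |
| bases ≥10× (cohort mean) | ≥ 0.95 | inclusive |
| bases <20× in *every* sample | < 0.20 | strict |
| case vs control mean depth | ≤ 10% | relative to the larger group mean |
| sample mean depth (cohort-wide) | ≥ 50× | per-sample QC |
| sample bases <20× (cohort-wide) | ≤ 0.20 | per-sample QC |

The between-group rule is interpreted as a *relative* difference because it
is scale-free across capture batches; an absolute mode
(`relative_mean_diff=False`, bound in depth units) is provided since the
original wording does not disambiguate. Per-sample QC bounds are not
numerically specified in the source design (its supplement is not public);
the defaults reuse the gene-level depth conventions cohort-wide. Group means
are computed over QC-passing samples only, and each excluded gene is
reported with the first rule it failed, in the fixed order above.

## Filter tiers

Strict tier: PASS, protein-altering, absent from the population resource,
CADD PHRED ≥ 20. Permissive tier: PASS, protein-altering, AF ≤ 0.01 with
absent counting as rare, no CADD bound. Decisions embedded here:

* The rarity bound is **inclusive** (≤ 0.01); the source design prints both
  "< 0.01" and "≤ 0.01" in different places.
* A recorded population frequency of exactly 0 is normalized to *absent*:
  a frequency resource that has never observed the allele prints 0 for the
  same state.
* A missing CADD score **fails** any CADD-thresholded profile
  (conservative: an unscorable variant is not assumed deleterious).
* stop-lost is part of the protein-altering class.
* Every strict-tier variant passes the permissive tier by construction
  (absent ⊆ rare; dropping the CADD bound only loosens) — enforced by a
  property test on generated cohorts.
* Variants annotated to several overlapping genes keep the first symbol
  (logged); double-counting a physical variant in two genes would correlate
  the per-gene tests.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at the
study's scale: 37 enrolled cases (30 + 7 across two subpopulations, the
minority one consanguineous; 2 cases planted to fail sample QC, leaving 35)
vs 38 controls; 7,500 genes; protein-altering consequence mix 96.9% missense,
2.1% stop, 1.0% splice; AF absent with probability 0.6, otherwise log-uniform
on [1e-6, 1e-2]; CADD above 20 with probability 0.6.

Carrier events are drawn per gene × sample (background probability 0.01;
0.25 for the 10 planted risk genes in cases) and then dressed with
variant-level annotations — exactly the generative structure the collapsing
statistic assumes. Values the study conditions do not fix were chosen once as
field-plausible: homozygous dosage fraction 0.02 (doubled in the
consanguineous stratum), Poisson(0.05) extra variants per carrier event,
decoy variants at rate 0.002 per gene-sample cycling through the three
rejection modes (non-PASS filter, AF = 0.05, non-coding consequence), 20
uneven-coverage genes cycling through the four harmonization rules, coverage
baselines Normal(100×, 8×) per gene with Normal(0, 5×) per-sample noise and
planted failures at Normal(30×, 3×).

What the generator deliberately does **not** model: linkage and shared
haplotypes, relatedness, true runs of homozygosity (the consanguineous
stratum only scales the homozygote rate), per-gene mutability differences,
annotation errors, and real genome coordinates (genes occupy disjoint 2 kb
intervals on one synthetic contig). Passing tests on this cohort therefore
demonstrate the pipeline's statistical correctness under its own model — not
robustness to stratification, cryptic relatedness or annotation noise in
real cohorts.

Determinism: one integer seed; each bundle section draws from its own
`default_rng([seed, stream])` sub-generator in a documented order, so equal
configs produce byte-identical bundles and individual files can be
regenerated independently.

### Power oracle

`expected_power` enumerates a ~ Binomial(n_cases, p_risk) ×
c ~ Binomial(n_controls, p_background) exactly and sums the probability mass
where the Fisher p-value clears α (the a = c = 0 cell counts as a
non-discovery: such a gene never enters the matrix). At the default
conditions (0.25 vs 0.01, 35 vs 38) the per-gene power at α = 0.05 is 0.945;
realized recovery across seeded cohorts is checked against this within
binomial error (`analysis/04_power_check.py`).

## Numerical and formatting choices

* Fisher: hypergeometric pmf over the support via scipy, memoized per table;
  the minimum-likelihood comparison uses the 1 + 1e-7 relative tolerance
  convention so ties are grouped as R groups them. Verified against exact
  rational-arithmetic enumeration to 1e-12 on randomized tables (margins ≤
  60) and against `scipy.stats.fisher_exact`.
* Hypergeometric tails: log-space accumulation (logpmf + logsumexp); k = 0
  short-circuits to 1. Verified against exact enumeration for all N ≤ 25 and
  against `scipy.stats.hypergeom.sf`.
* Rank test: `scipy.stats.mannwhitneyu`, two-sided, exact where scipy's
  method selection allows; checked against a 10,000-draw permutation oracle.
  The subcohort comparison uses the *unpaired* rank-sum test — the strata are
  independent samples of unequal size, so a signed-rank (paired) test is
  undefined for them, whatever the original analysis called it.
* Output tables fix floats to scientific notation with 6 significant digits,
  making re-runs byte-identical.
* Problem sizes in tests and drivers (7,500-gene default bundle; 300-gene
  structural bundle; 250–300 randomized oracle instances) were chosen to
  exercise the full default conditions while keeping a complete run in the
  low minutes on one CPU.

## Known limitations

* One gene symbol per variant; overlapping-gene burden is not double-counted.
* No covariate adjustment (no logistic/SKAT-style models), no relatedness or
  ancestry correction — the design assumes these were handled upstream or by
  cohort construction.
* Homozygous calls on male X are not special-cased (no sex data model).
* The gnomAD-style AF is a single global frequency; population-maximum
  frequencies are not consulted.
* Table 1-style published enrichment p-values from annotation-service
  pipelines are not reproducible locally (database- and option-dependent);
  the local over-representation engine is the stand-in and is validated
  against enumeration, not against those printed values.
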