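# Methods

## The load-outlier model

For each gene g, the analysis observes two counts: `load_control(g)`, the
number of distinct qualifying variants with at least one carrier in the
control (normal-hearing) group, and `load_case(g)`, the same in the case
(hearing-impaired) group. Presence, not allele count, defines load: a
variant carried by ten controls contributes one unit, the same as a
singleton. Loads are not normalised by group size; an overall imbalance in
group sizes shifts every gene alike and is absorbed by the regression.
This is a deliberate simplification — under extreme imbalance the
per-gene presence counts saturate differently and the linear fit is only
an approximation (see Limitations).

An ordinary least-squares line with intercept predicts case load from
control load across all genes with nonzero load in either group. The
residual r_g = y_g − (β̂ x_g + α̂) measures case-specific excess (positive)
or deficit (negative). Residual quartiles Q1 and Q3 are computed by
linear interpolation at fractional position p·(n−1) (the "type 7"
convention); with D = Q3 − Q1, the outlier fences are

    r_g > Q3 + 6·D   →  outlier in the case group
    r_g < Q1 − 6·D   →  outlier in the control group

Comparisons are strict, so when D = 0 (e.g. a perfect fit) nothing is
called. The 6·D multiplier is four times Tukey's conventional 1.5·IQR
fence: the rule is intentionally conservative, selecting only genes whose
excess is extreme relative to the bulk of the residual distribution.
Control-group outliers are retained because rare variants may protect
from, as well as predispose to, the phenotype.

## Qualifying variants

A variant qualifies when its minor allele frequency is **strictly** below
`maf_threshold` (default 0.10) and at least one impact criterion fires
(OR combination):

| criterion | field | default threshold |
|---|---|---|
| protein impact | `cadd` (phred-scaled) | ≥ 20 |
| splice impact | `spliceai` (delta, [0, 1]) | ≥ 0.5 |
| regulatory | `utr5_flag` (boolean) | flag set |

Two MAF modes exist: `nfe` (the Non-Finnish European reference frequency,
appropriate for a largely European cohort) and `max_population` (the
maximum frequency across all populations present, conservative for
diverse cohorts). A missing score fails its own criterion by default
(`missing_score_rule="pass_criterion"` inverts this); a missing NFE
frequency in nfe mode is treated as 0.0 with a warning — absence from
the reference panel is read as rarity — or the variant can be excluded
outright (`missing_nfe_rule="exclude"`). The numeric cut-offs are
conventional operating points for these predictors, not settled truths;
every threshold is configurable and recorded in run manifests, and the
pipeline's conclusions should be read as parameterised by them.

Filtering conserves records (qualifying + rejected = input, one reason
per rejected record, MAF checked before impact), is idempotent on its own
output, and is monotone in its thresholds; the test suite checks all
three properties on ~10,000-variant synthetic tables.

## Enrichment

Outlier lists are tested against curated gene sets by the upper-tail
hypergeometric probability P(X ≥ k), with X the overlap between a
uniformly drawn list of size n and the K set members inside the universe
of N genes. The universe is the set of genes appearing in the load table
— genes with at least one qualifying variant — because only those could
ever have been called outliers; the nominal set size is always
intersected with the universe. The test is one-sided (enrichment only).
Symbols match exactly after upper-casing; alias resolution is out of
scope. P-values from all tests in a run (every list × set pair) form one
family and are adjusted together, Benjamini–Hochberg by default or
Bonferroni on request; significance is declared at adjusted p < 0.05.

## Cohort rules

Participants enter the analysis if aged strictly over 55 (configurable)
and free of exclusion flags such as another ear disease; rows failing
inclusion are logged with reasons, never silently dropped. Participants
with an `unknown` phenotype are excluded from both groups rather than
defaulted to control — the central lesson of the misclassification
experiment is that a contaminated control group is worse than a smaller
one. Sex-specific analyses keep only participants whose sex assigned at
birth is "Male" or "Female" and whose recorded gender matches it; the
default match is strict string equality, with an optional synonym table
({"man"→"Male", "woman"→"Female"}, case-insensitive) for cohorts that
record gender in free text. Strata whose smaller phenotype group falls
below `min_stratum_size` (default 50) are reported as skipped rather than
analysed. Summary percentages are rounded half-up to integers, so the two
group percentages may sum to 99–101.

## The synthetic generator

The generator targets the presence-based load statistic directly rather
than simulating diploid genotypes. Per gene and **true** group, the
number of distinct qualifying variants is negative-binomial with mean
`baseline_rate × multiplier` and variance μ + αμ² (α = `dispersion`;
Poisson at α = 0). The multiplier is `signal_multiplier` for signal genes
in the case group, `variable_multiplier` for variable genes in both
groups, else 1. Each variant receives 1 + Poisson(`mean_extra_carriers`)
carriers from its true group. Misclassification is one-directional —
a fraction m of true cases is relabelled "normal", exactly
round(m·n_cases) of them — because the mechanism being modelled is
undiagnosed mild disease, not symmetric label noise. For a case-group
variant with c carriers, the number of carriers landing in the observed
control group is drawn from the hypergeometric law induced by the
mislabelled subset (the exact conditional distribution given the flipped
set and exchangeable carriers); carrier identities are not materialised,
so carrier sharing across variants is not modelled. Decoy variants — a
configurable fraction of the emitted table — fail the default filter,
half on frequency (MAF in (0.10, 0.5)) and half on impact scores, so both
rejection branches are exercised end to end. Planted variants qualify
through a randomly chosen route (70% protein, 20% splice, 10% 5'UTR) and
a tenth of the non-deciding scores are missing, exercising the OR
combination and the missing-score rule without changing the qualifying
set.

Defaults: 2,000 genes, 500 controls + 500 cases, baseline 5 variants per
gene per group, dispersion 0.05, 20 signal genes at multiplier 10, 100
variable genes at multiplier 3, decoy fraction 0.1. The gene count,
signal-set size and case:control balance are a desk-scale reduction of a
biobank exome comparison. The signal multiplier is set where a planted
gene is reliably callable by the 6·IQR fence: with baseline b and
multiplier s, a signal gene's expected residual is roughly b(s−1) while
the fence sits near Q3 + 6·IQR ≈ 8.8σ of the null residual spread
(≈ 8.8·√b for near-Poisson counts), so at b = 5 multipliers below ~6
leave planted genes under the fence almost surely and multipliers around
10 clear it with margin. That strong operating point is the premise of
the contamination experiment — degradation is only measurable from a
state in which recovery works — and matches the biology the fence is
designed for: genes with an order-of-magnitude case excess, as a
largely monogenic deafness gene would show in an enriched cohort.
Dispersion 0.05 keeps mild overdispersion (real per-gene variant counts
are not Poisson) without drowning the signal.

What the generator does **not** emulate: linkage disequilibrium,
realistic site-frequency spectra, ancestry-specific allele-frequency
structure, gene length (all genes share one baseline), covariates such
as age or sex within a stratum, and sequencing or annotation error.
Passing tests therefore show that the pipeline recovers the statistical
structure it assumes, not that it is robust to everything real exomes do.

## The misclassification sweep

`sweep_misclassification` runs the full pipeline over a grid of
contamination levels (default m ∈ {0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7}; the
0.7 point is an illustrative rendering of a scenario in which a
~48%-prevalence condition yields only a ~15% diagnosed case group), with
20 replicates per level by default. Per replicate it records the two
outlier counts, signal-gene sensitivity (recovered fraction of planted
signal genes among case-group outliers) and the raw/adjusted enrichment
p-values of both sets; the summary reports per-level means and the
Spearman correlation of mean sensitivity (and mean −log10 adjusted
deafness p) with m. Replicate seeds derive from
`SeedSequence([master, m_index, replicate])`, recorded in the manifest,
so any cell of the grid can be rerun in isolation. Contamination attacks
the contrast from both sides: flipped cases carry case variants into the
control column (raising x for signal genes, hence their predicted load)
and shrink the observed case group (lowering y), so residuals collapse
monotonically in m.

## Numerical choices

- OLS via `scipy.stats.linregress`; residuals of a fit with intercept sum
  to zero within 1e−9·(number of genes), asserted in tests.
- Quartiles via `numpy.quantile(..., method="linear")`; an independent
  sorted-array implementation is the test oracle.
- Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, N, K, n)`,
  exact against exhaustive enumeration for all parameter combinations
  with N ≤ 12 (and k = 0 short-circuits to exactly 1.0).
- Adjusted p-values via `statsmodels.stats.multitest.multipletests`;
  a by-hand step-up implementation is the test oracle.
- −log10 of adjusted p-values floors p at 1e−300 before the log.
- Degenerate inputs raise typed errors naming the condition (fewer than
  3 genes, constant predictor, fewer than 2 residuals) instead of
  producing NaNs.
- Enrichment type-I calibration is checked on a geometry (universe 5,000,
  set 1,000, list 250) where the discrete null's attainable level at
  p < 0.05 is 4.7%, close enough to nominal for a two-sided band; at
  small (N, K, n) the discreteness of the hypergeometric makes the
  attained level far below nominal, which is a property of the test, not
  a bug.

## Validation problem sizes

The test suite validates the outlier rule against brute force on 500
random tables of up to 50 genes; filter invariants on ~10,000 variants;
recovery and degradation on the default 2,000-gene generator with 20
replicates per condition; and enrichment calibration on 1,000 replicates.
These sizes were chosen as the package's own desk-scale operating points
for routine validation.

## Limitations

- The fence rule inherits the weaknesses of OLS: a handful of extreme
  genes influence both the fitted line and D. The 6·IQR multiplier makes
  calls conservative but thresholds themselves are sample-dependent.
- Covariate adjustment (age, sex within a stratum), gene-length
  correction, robust or quantile regression, and carrier-count-weighted
  loads are explicitly out of scope.
- With very unbalanced groups the unnormalised presence-load regression
  can be mis-calibrated; the control group is always the predictor.
- Whether a real analysis of this design used an intercept, a particular
  quartile convention, or allele-count loads can differ between
  implementations; these choices are pinned here (intercept: yes;
  quartiles: type 7; loads: presence) and surfaced in run manifests so
  alternatives can be compared.
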