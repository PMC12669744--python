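# phenoload

Gene-level variant-load outlier analysis for case-control cohorts, with a
synthetic-cohort generator and a phenotype-misclassification experiment.

## The problem

Age-related hearing loss (ARHL) and other common, late-onset conditions are
increasingly studied in biobanks that pair exome or genome sequencing with
shallow phenotyping — a questionnaire answer or a diagnosis code instead of
an audiogram. A simple way to look for genes involved in such a condition is
to compare the *variant load* of each gene between phenotype groups: count
the distinct rare, high-impact ("qualifying") variants seen in the
normal-hearing group and in the hearing-impaired group, and ask which genes
carry far more load in one group than the other group's load predicts.

The catch is the control group. A common condition that often goes
undiagnosed — mild hearing loss is the canonical example — leaves many true
cases sitting in a diagnosis-defined "control" group. This package
implements the load-outlier analysis *and* a simulation framework for
quantifying exactly how much that contamination costs.

## The method

1. **Filter** annotated variants to the qualifying set: minor allele
   frequency below 10% (strict), under either the Non-Finnish European
   frequency or the maximum frequency across populations, *and* high
   predicted impact by any of: a phred-scaled deleteriousness score
   (CADD ≥ 20), a splice-impact delta (SpliceAI ≥ 0.5), or a high-impact
   5'UTR flag.
2. **Count loads** per gene: x_g = qualifying variants present (≥ 1 carrier)
   in controls, y_g = the same in cases.
3. **Regress** y on x by ordinary least squares across genes and take
   residuals r_g = y_g − (β̂x_g + α̂). With Q1, Q3 the residual quartiles
   and D = Q3 − Q1, a gene is an outlier in the case group if
   r_g > Q3 + 6D, and in the control group if r_g < Q1 − 6D. Both
   directions matter: rare variants may protect as well as predispose.
4. **Test enrichment** of each outlier list in curated gene sets (e.g. known
   deafness genes vs. "variable" genes that are noisy in any sequencing
   experiment) by the upper-tail hypergeometric probability
   P(X ≥ k) for X ~ Hypergeom(N, K, n), with Benjamini–Hochberg adjustment
   across all tests in a run. Enrichment in deafness genes suggests
   biological signal; enrichment in variable genes suggests artefact.

The simulator plants signal genes (case-load multiplier), variable genes
(inflated in both groups), and a tunable fraction *m* of true cases
mislabelled as controls; `sweep_misclassification` measures how sensitivity
and enrichment decay as *m* grows.

## Worked example

```python
from phenoload import SimulationConfig, sweep_misclassification
from phenoload.experiment import sweep_report

config = SimulationConfig(n_genes=1000, n_controls=300, n_cases=300,
                          n_signal_genes=15, n_variable_genes=50)
sweep = sweep_misclassification(config, (0.0, 0.3, 0.7), replicates=10, seed=7)
print(sweep_report(sweep))
```

prints

```
| m | mean sensitivity | mean -log10(adj deafness p) | deafness significant | variable significant |
|---|---|---|---|---|
| 0 | 0.927 | 29.11 | 100% | 0% |
| 0.3 | 0.487 | 13.64 | 100% | 0% |
| 0.7 | 0.093 | 2.16 | 50% | 0% |

Spearman(mean sensitivity, m) = -1.000; Spearman(mean -log10 adj p, m) = -1.000
```

With clean labels (m = 0) the pipeline recovers 93% of the 15 planted
signal genes and the deafness set is decisively enriched in every
replicate. When 70% of true cases hide in the control group — roughly the
scenario of a 48%-prevalence condition of which only a 15% sliver is
diagnosed — recovery collapses to 9% and enrichment is lost half the time,
while the variable-gene set never lights up. The same chain is available
from the shell:

```bash
phenoload simulate --out-dir sim/
phenoload filter --variants sim/variants.tsv --out sim/qualifying.tsv
phenoload outliers --variants sim/qualifying.tsv --out-prefix sim/outliers
phenoload enrich --outliers sim/outliers.genes.tsv --sets sim/gene_sets.gmt --out sim/enrichment.tsv
phenoload experiment sweep --out-dir sim/sweep --seed 1
```

## Layout

- `phenoload.cohort` — participants, inclusion/exclusion, stratification, summaries
- `phenoload.filtering` — qualifying-variant selection (TSV or VCF input)
- `phenoload.outliers` — per-gene loads, load regression, 6·IQR fence rule
- `phenoload.enrichment` — hypergeometric tests, gene-set IO, p-value adjustment
- `phenoload.simulate` — synthetic cohorts with planted structure
- `phenoload.experiment` — comparison runner, misclassification sweep, reports

See `docs/methods.md` for the model, parameter defaults and limitations.
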