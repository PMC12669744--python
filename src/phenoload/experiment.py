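"""End-to-end comparison runs and the misclassification sweep.

``run_comparison`` chains the pipeline stages — cohort stratification,
variant filtering, load regression, outlier calling, enrichment — for one
comparison, recording every configuration value in a manifest so runs are
reproducible.  Strata below the minimum size yield a structured "skipped"
record rather than an analysis.

``sweep_misclassification`` quantifies how control-group contamination
degrades recovery of planted signal genes: for each contamination level m
it simulates replicate cohorts in which a fraction m of true cases is
labelled "normal", runs the full pipeline, and records signal-gene
sensitivity and deafness-set enrichment.  The summary reports per-m means
and the Spearman correlation of mean sensitivity with m (expected to be
negative: contamination dilutes the case-control contrast from both sides,
inflating control loads and deflating case loads).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import __version__
from .cohort import CohortDesign, apply_sex_exclusion
from .enrichment import (
    EnrichmentResult,
    GeneSet,
    adjust_pvalues,
    enrich,
)
from .errors import ValidationError
from .filtering import FilterPolicy, apply_filters
from .outliers import OutlierCalls, call_outliers, compute_gene_loads, fit_load_regression
from .simulate import (
    CASE_LABEL,
    CONTROL_LABEL,
    DEAFNESS_SET_NAME,
    VARIABLE_SET_NAME,
    SimulationConfig,
    make_gene_sets,
    simulate_cohort,
    simulate_variants,
)

logger = logging.getLogger(__name__)

DEFAULT_M_GRID: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7)
DEFAULT_REPLICATES = 20
P_FLOOR = 1e-300  # avoid -log10(0) when the tail underflows


@dataclass(frozen=True)
class ComparisonSpec:
    """One cell of a comparison matrix: stratum, group labels, policy."""

    name: str = "all"
    sex: str | None = None
    ancestry: str | None = None
    control_label: str = CONTROL_LABEL
    case_label: str = CASE_LABEL
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    adjust_method: str = "bh"
    min_stratum_size: int = 50

    def __post_init__(self) -> None:
        if self.control_label == self.case_label:
            raise ValidationError("control and case labels must differ")


@dataclass
class ComparisonResult:
    name: str
    skipped: bool
    skip_reason: str | None
    calls: OutlierCalls | None
    enrichments: list[EnrichmentResult]
    manifest: dict


def _stratum_members(cohort: CohortDesign, spec: ComparisonSpec) -> CohortDesign:
    base = apply_sex_exclusion(cohort) if spec.sex is not None else cohort
    members = [
        p
        for p in base.participants
        if (spec.sex is None or p.sex_at_birth == spec.sex)
        and (spec.ancestry is None or p.ancestry == spec.ancestry)
    ]
    return CohortDesign(
        name=f"{cohort.name}[{spec.name}]",
        phenotyping_mode=cohort.phenotyping_mode,
        maf_mode=cohort.maf_mode,
        participants=members,
    )


def run_comparison(
    cohort: CohortDesign,
    variants: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    spec: ComparisonSpec,
) -> ComparisonResult:
    """Run one comparison end to end, or mark it skipped.

    Carrier columns are looked up by the spec's group labels.  The
    enrichment universe is the set of genes with at least one qualifying
    variant in either group; both directional outlier lists are tested
    against every gene set and adjusted as one family.
    """
    manifest = {
        "comparison": spec.name,
        "sex": spec.sex,
        "ancestry": spec.ancestry,
        "control_label": spec.control_label,
        "case_label": spec.case_label,
        "policy": spec.policy.to_dict(),
        "adjust_method": spec.adjust_method,
        "min_stratum_size": spec.min_stratum_size,
        "gene_sets": {gs.name: len(gs) for gs in gene_sets},
        "phenoload_version": __version__,
    }
    stratum = _stratum_members(cohort, spec)
    counts = {
        label: sum(1 for p in stratum.participants if p.phenotype_label == label)
        for label in (spec.control_label, spec.case_label)
    }
    manifest["stratum_group_sizes"] = counts
    if min(counts.values()) < spec.min_stratum_size:
        return ComparisonResult(
            name=spec.name,
            skipped=True,
            skip_reason="skipped: insufficient participants",
            calls=None,
            enrichments=[],
            manifest=manifest,
        )

    try:
        qualifying, rejected = apply_filters(variants, spec.policy)
        manifest["n_variants_qualifying"] = int(len(qualifying))
        manifest["n_variants_rejected"] = int(len(rejected))
        loads = compute_gene_loads(qualifying, spec.control_label, spec.case_label)
        calls = call_outliers(fit_load_regression(loads))
        universe = loads["gene"].tolist()
        results: list[EnrichmentResult] = []
        for list_name, gene_list in (
            ("outliers_case", calls.outliers_case),
            ("outliers_control", calls.outliers_control),
        ):
            results.extend(
                enrich(gene_list, gene_sets, universe, list_name=list_name)
            )
        results = adjust_pvalues(results, method=spec.adjust_method)
    except Exception as exc:
        raise type(exc)(f"[comparison {spec.name}] {exc}") from exc
    return ComparisonResult(
        name=spec.name,
        skipped=False,
        skip_reason=None,
        calls=calls,
        enrichments=results,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Misclassification sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Replicate-level results, per-m summary, and the monotone-trend statistic."""

    results: pd.DataFrame
    summary: pd.DataFrame
    spearman_sensitivity_vs_m: float
    spearman_neglog_p_vs_m: float
    manifest: dict


def replicate_seed(master_seed: int, m_index: int, replicate: int) -> int:
    """Derive a per-replicate seed from (master, grid position, replicate).

    The counter scheme is recorded in the sweep manifest so any replicate
    can be rerun in isolation.
    """
    seq = np.random.SeedSequence([int(master_seed), int(m_index), int(replicate)])
    return int(seq.generate_state(1)[0]) % (2**31)


def run_replicate(config: SimulationConfig, policy: FilterPolicy | None = None) -> dict:
    """Simulate one cohort, run the pipeline, score recovery.

    Sensitivity is the fraction of planted signal genes called case-group
    outliers.  Enrichment p-values are adjusted within the replicate's
    four-test family (two directional lists x two sets).
    """
    policy = policy or FilterPolicy()
    _cohort, truth = simulate_cohort(config)
    variants = simulate_variants(config, truth)
    deafness, variable = make_gene_sets(truth)

    qualifying, _rejected = apply_filters(variants, policy)
    loads = compute_gene_loads(qualifying, CONTROL_LABEL, CASE_LABEL)
    calls = call_outliers(fit_load_regression(loads))
    universe = loads["gene"].tolist()
    results: list[EnrichmentResult] = []
    for list_name, gene_list in (
        ("outliers_case", calls.outliers_case),
        ("outliers_control", calls.outliers_control),
    ):
        results.extend(
            enrich(gene_list, [deafness, variable], universe, list_name=list_name)
        )
    results = adjust_pvalues(results)

    def pick(list_name: str, set_name: str) -> EnrichmentResult:
        return next(
            r for r in results if r.list_name == list_name and r.set_name == set_name
        )

    deaf = pick("outliers_case", DEAFNESS_SET_NAME)
    vari = pick("outliers_case", VARIABLE_SET_NAME)
    recovered = set(calls.outliers_case) & truth.signal_genes
    return {
        "seed": config.seed,
        "misclassification_rate": config.misclassification_rate,
        "n_outliers_case": len(calls.outliers_case),
        "n_outliers_control": len(calls.outliers_control),
        "sensitivity": len(recovered) / len(truth.signal_genes),
        "deafness_p": deaf.p_value,
        "deafness_adj_p": deaf.adjusted_p,
        "deafness_significant": bool(deaf.significant),
        "variable_p": vari.p_value,
        "variable_adj_p": vari.adjusted_p,
        "variable_significant": bool(vari.significant),
    }


def _trend(x: Sequence[float], y: Sequence[float]) -> float:
    # a constant series has no defined rank correlation; report no trend
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(x, y).statistic
    return 0.0 if math.isnan(rho) else float(rho)


def sweep_misclassification(
    base_config: SimulationConfig,
    m_values: Sequence[float] = DEFAULT_M_GRID,
    replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    policy: FilterPolicy | None = None,
) -> SweepResult:
    """Run the contamination grid and summarise signal degradation.

    For each m in ``m_values``, ``replicates`` independent cohorts are
    simulated with that misclassification rate (all other parameters from
    ``base_config``) and scored.  The summary holds per-m means; the trend
    statistics are Spearman correlations of those means against m.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if any(not (0.0 <= m <= 1.0) for m in m_values):
        raise ValidationError("misclassification levels must be in [0, 1]")
    master = base_config.seed if seed is None else int(seed)
    rows = []
    for i_m, m in enumerate(m_values):
        for j in range(replicates):
            config = dataclasses.replace(
                base_config,
                misclassification_rate=float(m),
                seed=replicate_seed(master, i_m, j),
            )
            row = run_replicate(config, policy=policy)
            row["replicate"] = j
            rows.append(row)
    results = pd.DataFrame(rows)
    results["neglog10_deafness_adj_p"] = -np.log10(
        results["deafness_adj_p"].clip(lower=P_FLOOR)
    )
    summary = (
        results.groupby("misclassification_rate")
        .agg(
            mean_sensitivity=("sensitivity", "mean"),
            mean_neglog10_deafness_adj_p=("neglog10_deafness_adj_p", "mean"),
            mean_outliers_case=("n_outliers_case", "mean"),
            mean_outliers_control=("n_outliers_control", "mean"),
            deafness_significant_fraction=("deafness_significant", "mean"),
            variable_significant_fraction=("variable_significant", "mean"),
        )
        .reset_index()
    )
    manifest = {
        "base_config": base_config.to_dict(),
        "m_values": list(map(float, m_values)),
        "replicates": int(replicates),
        "master_seed": master,
        "seed_scheme": "SeedSequence([master, m_index, replicate]) % 2**31",
        "policy": (policy or FilterPolicy()).to_dict(),
        "phenoload_version": __version__,
    }
    return SweepResult(
        results=results,
        summary=summary,
        spearman_sensitivity_vs_m=_trend(
            summary["misclassification_rate"], summary["mean_sensitivity"]
        ),
        spearman_neglog_p_vs_m=_trend(
            summary["misclassification_rate"], summary["mean_neglog10_deafness_adj_p"]
        ),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def comparison_report(results: Sequence[ComparisonResult]) -> str:
    """Markdown matrix of outlier counts with enrichment flags.

    A dagger marks deafness-set enrichment, an asterisk variable-set
    enrichment (adjusted p < 0.05); skipped strata render as "-".
    """
    if not results:
        raise ValidationError("no comparison results to report")
    lines = [
        "| Comparison | Outliers (case) | Outliers (control) |",
        "|---|---|---|",
    ]
    for res in results:
        if res.skipped:
            lines.append(f"| {res.name} | - | - |")
            continue
        cells = []
        for list_name, genes in (
            ("outliers_case", res.calls.outliers_case),
            ("outliers_control", res.calls.outliers_control),
        ):
            flags = ""
            for r in res.enrichments:
                if r.list_name == list_name and r.significant:
                    flags += "†" if r.set_name == DEAFNESS_SET_NAME else "*"
            cells.append(f"{len(genes)}{flags}")
        lines.append(f"| {res.name} | {cells[0]} | {cells[1]} |")
    return "\n".join(lines) + "\n"


def comparison_json(results: Sequence[ComparisonResult]) -> list[dict]:
    out = []
    for res in results:
        entry = {
            "comparison": res.name,
            "skipped": res.skipped,
            "skip_reason": res.skip_reason,
            "manifest": res.manifest,
        }
        if not res.skipped:
            entry["outliers_case"] = list(res.calls.outliers_case)
            entry["outliers_control"] = list(res.calls.outliers_control)
            entry["fit"] = res.calls.fit.summary()
            entry["enrichment"] = [r.to_dict() for r in res.enrichments]
        out.append(entry)
    return out


def sweep_report(sweep: SweepResult) -> str:
    lines = [
        "| m | mean sensitivity | mean -log10(adj deafness p) | "
        "deafness significant | variable significant |",
        "|---|---|---|---|---|",
    ]
    for row in sweep.summary.itertuples(index=False):
        lines.append(
            f"| {row.misclassification_rate:g} "
            f"| {row.mean_sensitivity:.3f} "
            f"| {row.mean_neglog10_deafness_adj_p:.2f} "
            f"| {row.deafness_significant_fraction:.0%} "
            f"| {row.variable_significant_fraction:.0%} |"
        )
    lines.append("")
    lines.append(
        f"Spearman(mean sensitivity, m) = {sweep.spearman_sensitivity_vs_m:.3f}; "
        f"Spearman(mean -log10 adj p, m) = {sweep.spearman_neglog_p_vs_m:.3f}"
    )
    return "\n".join(lines) + "\n"
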