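"""Synthetic cohorts and variant tables with planted structure.

The generator emulates the statistical skeleton of a biobank case-control
variant-load comparison:

* two phenotype groups ("normal" controls, "impaired" cases);
* per gene and per true group, a count of distinct qualifying variants
  drawn from a negative-binomial (Poisson when dispersion -> 0);
* a planted set of signal ("deafness") genes whose case-group rate is
  multiplied by ``signal_multiplier``;
* a planted set of "variable" genes inflated in both groups by
  ``variable_multiplier`` — noise-prone genes that should never look
  case-specific;
* phenotype misclassification: a fraction ``misclassification_rate`` of
  true cases is relabelled as controls, modelling people with undiagnosed
  mild hearing loss sitting in a diagnosis-defined control group.  The
  contamination is one-directional by design.

Variants are materialised in the flat annotation schema the filter
consumes.  Planted variants pass the default filter policy; a configurable
fraction of decoy variants fails it (half on frequency, half on impact) so
filtering is exercised end to end.  Carrier counts per variant are
1 + Poisson; carriers of case-group variants are split between observed
groups according to the mislabelled participants.

All outputs are pure functions of the configuration (seed included).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDesign, Participant
from .enrichment import GeneSet, write_gmt
from .errors import ValidationError
from .filtering import AF_PREFIX, CARRIER_PREFIX

logger = logging.getLogger(__name__)

CONTROL_LABEL = "normal"
CASE_LABEL = "impaired"
DEAFNESS_SET_NAME = "deafness"
VARIABLE_SET_NAME = "variable"

#: Ancestry labels and sampling weights, loosely mirroring a diverse
#: US-style biobank so stratified analyses have something to stratify on.
ANCESTRY_DISTRIBUTION: Mapping[str, float] = {
    "European": 0.57,
    "African/African American": 0.20,
    "American Admixed/Latino": 0.10,
    "East Asian": 0.04,
    "South Asian": 0.03,
    "Other": 0.06,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic cohort + variant table.

    ``baseline_rate`` is the expected number of distinct qualifying
    variants per gene per group under the null; ``dispersion`` is the
    negative-binomial overdispersion alpha (variance = mu + alpha * mu^2;
    0 gives Poisson).  ``signal_multiplier`` scales the case-group rate of
    signal genes; ``variable_multiplier`` scales both groups of variable
    genes.  ``misclassification_rate`` is the fraction of true cases
    observed as controls.
    """

    seed: int = 0
    n_genes: int = 2000
    n_controls: int = 500
    n_cases: int = 500
    baseline_rate: float = 5.0
    dispersion: float = 0.05
    n_signal_genes: int = 20
    signal_multiplier: float = 10.0
    n_variable_genes: int = 100
    variable_multiplier: float = 3.0
    misclassification_rate: float = 0.0
    decoy_fraction: float = 0.1
    mean_extra_carriers: float = 0.3

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if self.n_controls < 1 or self.n_cases < 1:
            problems.append("n_controls and n_cases must be >= 1")
        if self.baseline_rate <= 0:
            problems.append("baseline_rate must be > 0")
        if self.dispersion < 0:
            problems.append("dispersion must be >= 0")
        if self.n_signal_genes < 0 or self.n_variable_genes < 0:
            problems.append("planted gene counts must be >= 0")
        if self.n_signal_genes + self.n_variable_genes > self.n_genes:
            problems.append("n_signal_genes + n_variable_genes must be <= n_genes")
        if self.signal_multiplier < 1 or self.variable_multiplier < 1:
            problems.append("multipliers must be >= 1")
        if not (0.0 <= self.misclassification_rate <= 1.0):
            problems.append("misclassification_rate must be in [0, 1]")
        if not (0.0 <= self.decoy_fraction < 1.0):
            problems.append("decoy_fraction must be in [0, 1)")
        if self.mean_extra_carriers < 0:
            problems.append("mean_extra_carriers must be >= 0")
        if problems:
            raise ValidationError("invalid SimulationConfig: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class TruthLabels:
    """Ground truth for recovery scoring."""

    signal_genes: frozenset[str]
    variable_genes: frozenset[str]
    true_phenotype: Mapping[str, str]
    observed_phenotype: Mapping[str, str]

    @property
    def flipped(self) -> frozenset[str]:
        return frozenset(
            pid
            for pid, true in self.true_phenotype.items()
            if true == CASE_LABEL and self.observed_phenotype[pid] == CONTROL_LABEL
        )

    def to_dict(self) -> dict:
        return {
            "signal_genes": sorted(self.signal_genes),
            "variable_genes": sorted(self.variable_genes),
            "true_phenotype": dict(self.true_phenotype),
            "observed_phenotype": dict(self.observed_phenotype),
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Separate deterministic streams for cohort and variant generation.
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDesign, TruthLabels]:
    """Draw participants, plant signal/variable genes, apply mislabelling.

    Exactly ``round(misclassification_rate * n_cases)`` true cases receive
    the observed label "normal"; everything else is observed as truth.
    """
    config.validate()
    rng = _rng(config, 0)

    genes = gene_names(config.n_genes)
    planted = rng.choice(
        config.n_genes,
        size=config.n_signal_genes + config.n_variable_genes,
        replace=False,
    )
    signal = frozenset(genes[i] for i in planted[: config.n_signal_genes])
    variable = frozenset(genes[i] for i in planted[config.n_signal_genes:])

    n_total = config.n_controls + config.n_cases
    ids = [f"P{i:06d}" for i in range(n_total)]
    true_labels = [CONTROL_LABEL] * config.n_controls + [CASE_LABEL] * config.n_cases

    n_flips = round(config.misclassification_rate * config.n_cases)
    case_positions = np.arange(config.n_controls, n_total)
    flip_positions = set(
        rng.choice(case_positions, size=n_flips, replace=False).tolist()
    ) if n_flips else set()

    sexes = rng.choice(["Male", "Female"], size=n_total)
    ancestries = rng.choice(
        list(ANCESTRY_DISTRIBUTION),
        size=n_total,
        p=list(ANCESTRY_DISTRIBUTION.values()),
    )
    ages = rng.integers(56, 91, size=n_total)

    participants: list[Participant] = []
    true_phenotype: dict[str, str] = {}
    observed_phenotype: dict[str, str] = {}
    for i, pid in enumerate(ids):
        true = true_labels[i]
        observed = CONTROL_LABEL if i in flip_positions else true
        true_phenotype[pid] = true
        observed_phenotype[pid] = observed
        participants.append(
            Participant(
                participant_id=pid,
                phenotype_label=observed,
                age_years=float(ages[i]),
                sex_at_birth=str(sexes[i]),
                gender=str(sexes[i]),
                ancestry=str(ancestries[i]),
            )
        )
    cohort = CohortDesign(
        name=f"synthetic-seed{config.seed}",
        phenotyping_mode="diagnostic" if config.misclassification_rate > 0 else "self_report",
        maf_mode="max_population",
        participants=participants,
    )
    truth = TruthLabels(
        signal_genes=signal,
        variable_genes=variable,
        true_phenotype=true_phenotype,
        observed_phenotype=observed_phenotype,
    )
    return cohort, truth


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """Counts with variance mu + alpha*mu^2 via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def simulate_variants(config: SimulationConfig, truth: TruthLabels) -> pd.DataFrame:
    """Materialise the variant table implied by the truth labels.

    Per gene and TRUE group the number of distinct qualifying variants is
    negative-binomial with mean baseline_rate * multiplier(gene, group).
    Carrier counts are 1 + Poisson(mean_extra_carriers); for case-group
    variants the carriers are partitioned between observed groups by the
    hypergeometric law induced by the mislabelled-participant subset, so
    observed presence reflects the contamination.  Decoy variants (a
    ``decoy_fraction`` of the emitted table) fail the default filter, half
    on allele frequency and half on impact scores.
    """
    config.validate()
    rng = _rng(config, 1)
    genes = np.array(gene_names(config.n_genes))
    is_signal = np.isin(genes, sorted(truth.signal_genes))
    is_variable = np.isin(genes, sorted(truth.variable_genes))

    mult_control = np.where(is_variable, config.variable_multiplier, 1.0)
    mult_case = np.where(
        is_signal,
        config.signal_multiplier,
        np.where(is_variable, config.variable_multiplier, 1.0),
    )

    n_flipped = len(truth.flipped)
    frames: list[pd.DataFrame] = []
    for group, mult in ((CONTROL_LABEL, mult_control), (CASE_LABEL, mult_case)):
        counts = _negative_binomial(rng, config.baseline_rate * mult, config.dispersion)
        var_genes = np.repeat(genes, counts)
        n = var_genes.size
        group_size = config.n_controls if group == CONTROL_LABEL else config.n_cases
        carriers = np.minimum(
            1 + rng.poisson(config.mean_extra_carriers, size=n), group_size
        )
        if group == CASE_LABEL and n_flipped > 0:
            # Carriers drawn without replacement from the true case group:
            # the number landing in the mislabelled subset is hypergeometric.
            flipped_carriers = rng.hypergeometric(
                n_flipped, config.n_cases - n_flipped, carriers
            )
        else:
            flipped_carriers = np.zeros(n, dtype=int)
        if group == CONTROL_LABEL:
            c_normal, c_impaired = carriers, np.zeros(n, dtype=int)
        else:
            c_normal, c_impaired = flipped_carriers, carriers - flipped_carriers
        frames.append(
            _annotate_qualifying(rng, var_genes, c_normal, c_impaired)
        )

    qualifying = pd.concat(frames, ignore_index=True)
    # Decoys are decoy_fraction of the emitted table: n_d = n_q * f / (1 - f).
    n_decoys = round(len(qualifying) * config.decoy_fraction / (1 - config.decoy_fraction))
    if n_decoys > 0:
        decoys = _make_decoys(rng, config, genes, n_decoys, n_flipped)
        table = pd.concat([qualifying, decoys], ignore_index=True)
    else:
        table = qualifying
    table["variant_id"] = [
        f"chr1:{pos}:A:G" for pos in range(1, len(table) + 1)
    ]
    cols = [
        "variant_id",
        "gene",
        AF_PREFIX + "nfe",
        AF_PREFIX + "afr",
        "cadd",
        "spliceai",
        "utr5_flag",
        CARRIER_PREFIX + CONTROL_LABEL,
        CARRIER_PREFIX + CASE_LABEL,
    ]
    return table[cols]


def _annotate_qualifying(
    rng: np.random.Generator,
    var_genes: np.ndarray,
    carriers_normal: np.ndarray,
    carriers_impaired: np.ndarray,
) -> pd.DataFrame:
    """Frequencies and scores that pass the default policy.

    Each variant qualifies through one randomly chosen route — protein
    impact (high CADD), splice impact, or the 5'UTR flag — so the OR
    combination is exercised; a tenth of the non-deciding scores are
    missing, exercising the missing-score rule without changing the
    qualifying set.
    """
    n = var_genes.size
    af_nfe = rng.uniform(1e-4, 0.08, size=n)
    af_afr = np.clip(af_nfe * rng.uniform(0.5, 1.2, size=n), 0.0, 0.099)
    route = rng.choice(3, size=n, p=[0.7, 0.2, 0.1])
    cadd = np.where(route == 0, rng.uniform(20, 45, size=n), rng.uniform(0, 15, size=n))
    splice = np.where(
        route == 1, rng.uniform(0.5, 1.0, size=n), rng.uniform(0.0, 0.4, size=n)
    )
    utr5 = route == 2
    cadd = np.where((route != 0) & (rng.random(n) < 0.1), np.nan, cadd)
    splice = np.where((route != 1) & (rng.random(n) < 0.1), np.nan, splice)
    return pd.DataFrame(
        {
            "gene": var_genes,
            AF_PREFIX + "nfe": af_nfe,
            AF_PREFIX + "afr": af_afr,
            "cadd": cadd,
            "spliceai": splice,
            "utr5_flag": utr5,
            CARRIER_PREFIX + CONTROL_LABEL: carriers_normal,
            CARRIER_PREFIX + CASE_LABEL: carriers_impaired,
        }
    )


def _make_decoys(
    rng: np.random.Generator,
    config: SimulationConfig,
    genes: np.ndarray,
    n_decoys: int,
    n_flipped: int,
) -> pd.DataFrame:
    """Variants that fail the default filter, for exercising rejection paths.

    Half fail on MAF (common variants with passing scores), half on impact
    (rare variants below every score threshold); both branches of the
    filter are therefore exercised.  Decoy carriers belong to a random
    true group and are mislabelled like everyone else; decoys never enter
    the true load model (they are filtered out upstream).
    """
    var_genes = rng.choice(genes, size=n_decoys, replace=True)
    maf_fail = np.arange(n_decoys) < n_decoys // 2
    af_nfe = np.where(
        maf_fail, rng.uniform(0.10, 0.5, size=n_decoys), rng.uniform(1e-4, 0.08, size=n_decoys)
    )
    af_afr = np.clip(af_nfe * rng.uniform(0.8, 1.0, size=n_decoys), 0.0, 0.5)
    cadd = np.where(
        maf_fail, rng.uniform(20, 45, size=n_decoys), rng.uniform(0, 15, size=n_decoys)
    )
    splice = np.where(
        maf_fail, rng.uniform(0.5, 1.0, size=n_decoys), rng.uniform(0.0, 0.3, size=n_decoys)
    )
    in_control = rng.random(n_decoys) < 0.5
    carriers = np.minimum(
        1 + rng.poisson(config.mean_extra_carriers, size=n_decoys),
        min(config.n_controls, config.n_cases),
    )
    if n_flipped > 0:
        flipped_carriers = rng.hypergeometric(
            n_flipped, config.n_cases - n_flipped, carriers
        )
    else:
        flipped_carriers = np.zeros(n_decoys, dtype=int)
    c_normal = np.where(in_control, carriers, flipped_carriers)
    c_impaired = np.where(in_control, 0, carriers - flipped_carriers)
    return pd.DataFrame(
        {
            "gene": var_genes,
            AF_PREFIX + "nfe": af_nfe,
            AF_PREFIX + "afr": af_afr,
            "cadd": cadd,
            "spliceai": splice,
            "utr5_flag": np.zeros(n_decoys, dtype=bool),
            CARRIER_PREFIX + CONTROL_LABEL: c_normal,
            CARRIER_PREFIX + CASE_LABEL: c_impaired,
        }
    )


def write_simulation(
    out_dir: str | Path,
    config: SimulationConfig,
) -> dict[str, Path]:
    """Run the generator and write cohort TSV, variant TSV, GMT and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_cohort(config)
    variants = simulate_variants(config, truth)
    deafness, variable = make_gene_sets(truth)

    cohort_path = out / "cohort.tsv"
    pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "phenotype_label": p.phenotype_label,
                "age_years": p.age_years,
                "sex_at_birth": p.sex_at_birth,
                "gender": p.gender,
                "ancestry": p.ancestry,
                "exclusion_flags": "",
            }
            for p in cohort.participants
        ]
    ).to_csv(cohort_path, sep="\t", index=False)

    variants_path = out / "variants.tsv"
    variants.to_csv(variants_path, sep="\t", index=False)

    sets_path = out / "gene_sets.gmt"
    write_gmt([deafness, variable], sets_path, description="synthetic")

    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"config": config.to_dict(), **truth.to_dict()}, fh, indent=2)

    return {
        "cohort": cohort_path,
        "variants": variants_path,
        "gene_sets": sets_path,
        "truth": truth_path,
    }


def make_gene_sets(truth: TruthLabels) -> tuple[GeneSet, GeneSet]:
    """The two comparison sets: planted signal genes and planted variable genes."""
    if not truth.signal_genes:
        raise ValidationError("cannot build the deafness set: no signal genes planted")
    if not truth.variable_genes:
        raise ValidationError(
            "cannot build the variable set: no variable genes planted "
            "(set n_variable_genes >= 1)"
        )
    deafness = GeneSet(DEAFNESS_SET_NAME, frozenset(truth.signal_genes))
    variable = GeneSet(VARIABLE_SET_NAME, frozenset(truth.variable_genes))
    return deafness, variable
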