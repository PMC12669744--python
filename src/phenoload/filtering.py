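"""Qualifying-variant selection.

A variant qualifies when its minor allele frequency is below the threshold
(default 10%, strict) under the cohort's MAF mode, and at least one impact
predictor calls it high impact:

* a phred-scaled deleteriousness score (CADD-style) at or above ``cadd_min``;
* a splice-impact delta score (SpliceAI-style, in [0, 1]) at or above
  ``splice_min``;
* a 5'UTR high-impact flag.

The three criteria combine by OR.  Missing scores fail their own criterion
by default (configurable).  Two MAF modes are supported: ``nfe`` uses the
Non-Finnish European reference frequency, ``max_population`` the maximum
frequency across all populations present for the variant.

Variant tables are pandas DataFrames with columns ``variant_id`` (the
``chrom:pos:ref:alt`` VCF convention, 1-based), ``gene``, one ``AF_<pop>``
column per population, ``cadd``, ``spliceai``, ``utr5_flag`` and one
``carriers_<group>`` column per phenotype group.  A variant mapping to k
genes appears as k rows sharing its variant_id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

AF_PREFIX = "AF_"
CARRIER_PREFIX = "carriers_"
NFE_POPULATION = "nfe"
NFE_COLUMN = AF_PREFIX + NFE_POPULATION

REASON_MAF = "MAF ≥ {threshold:g}"
REASON_IMPACT = "no impact criterion met"
REASON_NFE_MISSING = "NFE frequency missing"


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds and modes for qualifying-variant selection.

    ``cadd_min`` and ``splice_min`` may be None to disable that criterion;
    ``use_utr5`` disables the flag criterion.  At least one impact
    criterion must remain enabled.
    """

    maf_threshold: float = 0.10
    maf_mode: str = "max_population"
    cadd_min: float | None = 20.0
    splice_min: float | None = 0.5
    use_utr5: bool = True
    missing_score_rule: str = "fail_criterion"
    missing_nfe_rule: str = "zero"  # or "exclude"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ValidationError(
                f"maf_threshold must be in (0, 1], got {self.maf_threshold}"
            )
        if self.maf_mode not in ("nfe", "max_population"):
            raise ValidationError(f"unknown maf_mode: {self.maf_mode!r}")
        if self.missing_score_rule not in ("fail_criterion", "pass_criterion"):
            raise ValidationError(
                f"unknown missing_score_rule: {self.missing_score_rule!r}"
            )
        if self.missing_nfe_rule not in ("zero", "exclude"):
            raise ValidationError(f"unknown missing_nfe_rule: {self.missing_nfe_rule!r}")
        if self.cadd_min is None and self.splice_min is None and not self.use_utr5:
            raise ValidationError("at least one impact criterion must be enabled")

    def to_dict(self) -> dict:
        return {
            "maf_threshold": self.maf_threshold,
            "maf_mode": self.maf_mode,
            "cadd_min": self.cadd_min,
            "splice_min": self.splice_min,
            "use_utr5": self.use_utr5,
            "missing_score_rule": self.missing_score_rule,
            "missing_nfe_rule": self.missing_nfe_rule,
        }


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant-gene record with annotations and per-group carrier counts."""

    variant_id: str
    gene: str
    population_afs: Mapping[str, float] = field(default_factory=dict)
    cadd_score: float | None = None
    splice_score: float | None = None
    utr5_flag: bool | None = None
    carriers_by_group: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError(f"variant {self.variant_id}: gene symbol is empty")
        for pop, af in self.population_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValidationError(
                    f"variant {self.variant_id}: allele frequency for {pop!r} "
                    f"out of [0, 1]: {af}"
                )
        if self.splice_score is not None and not (0.0 <= self.splice_score <= 1.0):
            raise ValidationError(
                f"variant {self.variant_id}: splice score out of [0, 1]: "
                f"{self.splice_score}"
            )

    @classmethod
    def from_row(cls, row: Mapping) -> "AnnotatedVariant":
        afs = {
            k[len(AF_PREFIX):]: float(v)
            for k, v in row.items()
            if k.startswith(AF_PREFIX) and _present(v)
        }
        carriers = {
            k[len(CARRIER_PREFIX):]: int(v)
            for k, v in row.items()
            if k.startswith(CARRIER_PREFIX) and _present(v)
        }
        return cls(
            variant_id=str(row["variant_id"]),
            gene=str(row["gene"]),
            population_afs=afs,
            cadd_score=_opt_float(row.get("cadd")),
            splice_score=_opt_float(row.get("spliceai")),
            utr5_flag=_opt_bool(row.get("utr5_flag")),
            carriers_by_group=carriers,
        )


def _present(v) -> bool:
    return v is not None and not (isinstance(v, float) and math.isnan(v))


def _opt_float(v) -> float | None:
    return float(v) if _present(v) else None


def _opt_bool(v) -> bool | None:
    if not _present(v):
        return None
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes", "t")
    return bool(v)


def effective_maf(
    variant: AnnotatedVariant | Mapping[str, float],
    mode: str,
    *,
    missing_nfe_rule: str = "zero",
) -> float:
    """The allele frequency a variant is filtered on under the given mode.

    ``nfe`` returns the Non-Finnish European frequency; ``max_population``
    the maximum over all populations present.  A missing NFE frequency in
    nfe mode is treated as 0.0 with a warning (absence from the reference
    panel read as rarity) unless ``missing_nfe_rule="exclude"``, in which
    case a :class:`UsageError` is raised for the caller to handle.
    """
    afs = variant.population_afs if isinstance(variant, AnnotatedVariant) else variant
    if mode == "nfe":
        if NFE_POPULATION in afs:
            return float(afs[NFE_POPULATION])
        if missing_nfe_rule == "zero":
            logger.warning("NFE frequency missing; treating as 0.0")
            return 0.0
        raise UsageError(REASON_NFE_MISSING)
    if mode == "max_population":
        if not afs:
            raise UsageError("no population allele frequencies present")
        return float(max(afs.values()))
    raise UsageError(f"unknown maf_mode: {mode!r}")


def passes_impact(
    variant: AnnotatedVariant | Mapping, policy: FilterPolicy
) -> bool:
    """True iff any enabled impact criterion is met (OR combination)."""
    if not isinstance(variant, AnnotatedVariant):
        variant = AnnotatedVariant.from_row(variant)
    missing_passes = policy.missing_score_rule == "pass_criterion"

    def crit(value: float | None, threshold: float | None) -> bool:
        if threshold is None:
            return False
        if value is None:
            return missing_passes
        return value >= threshold

    if crit(variant.cadd_score, policy.cadd_min):
        return True
    if crit(variant.splice_score, policy.splice_min):
        return True
    if policy.use_utr5:
        if variant.utr5_flag is None:
            return missing_passes
        return bool(variant.utr5_flag)
    return False


def _frame_effective_maf(df: pd.DataFrame, policy: FilterPolicy) -> tuple[pd.Series, pd.Series]:
    """Vectorised effective MAF plus a mask of rows with no usable frequency."""
    af_cols = [c for c in df.columns if c.startswith(AF_PREFIX)]
    if policy.maf_mode == "nfe":
        if NFE_COLUMN in df.columns:
            maf = df[NFE_COLUMN].astype(float)
        else:
            maf = pd.Series(np.nan, index=df.index)
        missing = maf.isna()
        if missing.any():
            if policy.missing_nfe_rule == "zero":
                logger.warning(
                    "%d variants missing NFE frequency; treated as 0.0", int(missing.sum())
                )
                maf = maf.fillna(0.0)
                missing = pd.Series(False, index=df.index)
        return maf, missing
    if not af_cols:
        raise FormatError("variant table has no AF_* columns")
    maf = df[af_cols].astype(float).max(axis=1)
    return maf, maf.isna()


def _frame_passes_impact(df: pd.DataFrame, policy: FilterPolicy) -> pd.Series:
    missing_passes = policy.missing_score_rule == "pass_criterion"

    def crit(col: str, threshold: float | None) -> pd.Series:
        if threshold is None or col not in df.columns:
            return pd.Series(False, index=df.index)
        vals = pd.to_numeric(df[col], errors="coerce")
        ok = vals >= threshold
        if missing_passes:
            ok = ok | vals.isna()
        return ok

    ok = crit("cadd", policy.cadd_min) | crit("spliceai", policy.splice_min)
    if policy.use_utr5:
        if "utr5_flag" in df.columns:
            flags = df["utr5_flag"].map(_opt_bool)
            utr_ok = flags.map(lambda v: missing_passes if v is None else bool(v))
        else:
            utr_ok = pd.Series(missing_passes, index=df.index)
        ok = ok | utr_ok
    return ok


def apply_filters(
    variants: pd.DataFrame, policy: FilterPolicy
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a variant table into qualifying variants and a rejection log.

    Returns ``(qualifying, rejections)``; rejections carry one reason per
    variant (MAF checked first, then impact).  Row counts are conserved:
    ``len(qualifying) + len(rejections) == len(variants)``.
    """
    for col in ("variant_id", "gene"):
        if col not in variants.columns:
            raise FormatError(f"variant table is missing required column {col!r}")
    if variants.empty:
        return variants.copy(), pd.DataFrame(columns=["variant_id", "gene", "reason"])

    maf, maf_missing = _frame_effective_maf(variants, policy)
    maf_ok = (maf < policy.maf_threshold) & ~maf_missing
    impact_ok = _frame_passes_impact(variants, policy)
    qualifying_mask = maf_ok & impact_ok

    reasons = pd.Series("", index=variants.index, dtype=object)
    reasons[~impact_ok] = REASON_IMPACT
    reasons[~(maf < policy.maf_threshold)] = REASON_MAF.format(
        threshold=policy.maf_threshold
    )
    reasons[maf_missing] = REASON_NFE_MISSING if policy.maf_mode == "nfe" else (
        "no allele frequency present"
    )

    qualifying = variants[qualifying_mask].copy()
    rejected = variants.loc[~qualifying_mask, ["variant_id", "gene"]].copy()
    rejected["reason"] = reasons[~qualifying_mask]
    logger.info(
        "filter: %d of %d variant records qualify", len(qualifying), len(variants)
    )
    return qualifying, rejected.reset_index(drop=True)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant table: tab-separated text, or VCF for ``.vcf`` files."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return read_variants_vcf(path)
    df = pd.read_csv(path, sep="\t")
    if "variant_id" not in df.columns or "gene" not in df.columns:
        raise FormatError(
            f"{path}: variant table must have variant_id and gene columns"
        )
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_variants_vcf(
    path: str | Path,
    *,
    gene_key: str = "GENE",
    cadd_key: str = "CADD",
    splice_key: str = "SPLICEAI",
    utr5_key: str = "UTR5",
    af_keys: Mapping[str, str] | None = None,
    carrier_keys: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read annotated variants from a VCF's INFO fields into the flat schema.

    INFO key names are configurable because annotation pipelines differ.
    ``af_keys`` maps population label -> INFO key (default: every key
    starting with ``AF_``, lower-cased label); ``carrier_keys`` maps group
    label -> INFO key (default: keys starting with ``CARRIERS_``).  A
    comma-separated gene field yields one record per gene.
    """
    from cyvcf2 import VCF

    records: list[dict] = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        alt = rec.ALT[0] if rec.ALT else "."
        variant_id = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
        genes = str(info.get(gene_key, "")).split(",") if gene_key in info else []
        genes = [g for g in (g.strip() for g in genes) if g]
        if not genes:
            logger.warning("%s: no gene annotation; record skipped", variant_id)
            continue
        base: dict = {"variant_id": variant_id}
        if af_keys:
            for pop, key in af_keys.items():
                if key in info:
                    base[AF_PREFIX + pop] = float(info[key])
        else:
            for key, val in info.items():
                if key.startswith("AF_"):
                    base[AF_PREFIX + key[3:].lower()] = float(val)
        if carrier_keys:
            for group, key in carrier_keys.items():
                if key in info:
                    base[CARRIER_PREFIX + group] = int(info[key])
        else:
            for key, val in info.items():
                if key.startswith("CARRIERS_"):
                    base[CARRIER_PREFIX + key[len("CARRIERS_"):].lower()] = int(val)
        if cadd_key in info:
            base["cadd"] = float(info[cadd_key])
        if splice_key in info:
            base["spliceai"] = float(info[splice_key])
        if utr5_key in info:
            base["utr5_flag"] = _opt_bool(info[utr5_key])
        for gene in genes:
            records.append({**base, "gene": gene})
    if not records:
        raise FormatError(f"{path}: no usable variant records")
    return pd.DataFrame.from_records(records)
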