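"""Participant-level cohort representation, inclusion/exclusion rules,
stratification and Table-1-style summaries.

A cohort compares a "normal" phenotype group against an "impaired" one.
Participants enter the analysis only if they are over the minimum age
(default 55 years) and carry no exclusion flags (e.g. another ear disease).
Sex-specific analyses additionally require sex assigned at birth to be
"Male" or "Female" and to match the recorded gender; everyone else is
excluded from those strata but kept for the all-participant comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

PHENOTYPE_LABELS = ("normal", "impaired", "unknown")
PHENOTYPING_MODES = ("audiometry", "self_report", "diagnostic")
MAF_MODES = ("nfe", "max_population")

#: Optional gender synonym table for the sex-consistency rule.  Off by
#: default: the strict rule requires recorded gender to equal sex at birth.
DEFAULT_GENDER_SYNONYMS: Mapping[str, str] = {"man": "Male", "woman": "Female"}

DEFAULT_MIN_AGE = 55.0
DEFAULT_MIN_STRATUM_SIZE = 50


@dataclass(frozen=True)
class Participant:
    participant_id: str
    phenotype_label: str
    age_years: float | None = None
    sex_at_birth: str | None = None
    gender: str | None = None
    ancestry: str | None = None
    exclusion_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.phenotype_label not in PHENOTYPE_LABELS:
            raise ValidationError(
                f"phenotype_label must be one of {PHENOTYPE_LABELS}, "
                f"got {self.phenotype_label!r}"
            )


@dataclass(frozen=True)
class Rejection:
    """One input row (or participant) excluded from analysis, with the reason."""

    participant_id: str
    reason: str


@dataclass
class CohortDesign:
    name: str
    phenotyping_mode: str = "self_report"
    maf_mode: str = "max_population"
    participants: list[Participant] = field(default_factory=list)
    rejection_log: list[Rejection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phenotyping_mode not in PHENOTYPING_MODES:
            raise ValidationError(
                f"phenotyping_mode must be one of {PHENOTYPING_MODES}, "
                f"got {self.phenotyping_mode!r}"
            )
        if self.maf_mode not in MAF_MODES:
            raise ValidationError(
                f"maf_mode must be one of {MAF_MODES}, got {self.maf_mode!r}"
            )
        ids = [p.participant_id for p in self.participants]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate participant_id(s): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.participants)


@dataclass(frozen=True)
class CohortSummary:
    """Counts and integer percentages for the two phenotype groups.

    Percentages are rounded half-up to the nearest integer, so the two
    group percentages may sum to 99, 100 or 101.  When no participant is
    classified the percentages are None rather than a division error.
    """

    total_participants: int
    total_classified: int
    n_normal: int
    n_impaired: int
    n_unknown: int
    normal_by_sex: dict[str, int]
    impaired_by_sex: dict[str, int]
    pct_normal: int | None
    pct_impaired: int | None

    def to_dict(self) -> dict:
        return {
            "total_participants": self.total_participants,
            "total_classified": self.total_classified,
            "n_normal": self.n_normal,
            "n_impaired": self.n_impaired,
            "n_unknown": self.n_unknown,
            "normal_by_sex": dict(self.normal_by_sex),
            "impaired_by_sex": dict(self.impaired_by_sex),
            "pct_normal": self.pct_normal,
            "pct_impaired": self.pct_impaired,
        }


@dataclass
class Stratum:
    label: str
    cohort: CohortDesign
    skipped: bool = False
    skip_reason: str | None = None


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-wards-up."""
    return int(math.floor(x + 0.5))


def _parse_flags(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return frozenset()
    text = str(raw).strip()
    if not text:
        return frozenset()
    return frozenset(f.strip() for f in text.split(";") if f.strip())


def _opt_str(raw) -> str | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    return text or None


def load_cohort_table(
    path: str | Path,
    *,
    name: str | None = None,
    phenotyping_mode: str = "self_report",
    maf_mode: str = "max_population",
    min_age: float = DEFAULT_MIN_AGE,
) -> CohortDesign:
    """Read a delimited participant table and apply the inclusion rules.

    Required columns: ``participant_id`` and ``phenotype_label``.  Optional:
    ``age_years``, ``sex_at_birth``, ``gender``, ``ancestry`` and
    ``exclusion_flags`` (semicolon-separated).  Rows failing inclusion
    (age not above ``min_age``, an exclusion flag, an unrecognised
    phenotype label) are recorded in the rejection log, never silently
    dropped; ``len(cohort) + len(cohort.rejection_log)`` always equals the
    number of data rows in the file.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype={"participant_id": str})
    return cohort_from_frame(
        df,
        name=name or path.stem,
        phenotyping_mode=phenotyping_mode,
        maf_mode=maf_mode,
        min_age=min_age,
    )


def cohort_from_frame(
    df: pd.DataFrame,
    *,
    name: str,
    phenotyping_mode: str = "self_report",
    maf_mode: str = "max_population",
    min_age: float = DEFAULT_MIN_AGE,
) -> CohortDesign:
    """Build a :class:`CohortDesign` from an in-memory participant table."""
    for col in ("participant_id", "phenotype_label"):
        if col not in df.columns:
            raise FormatError(f"cohort table is missing required column {col!r}")
    ids = df["participant_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"duplicate participant_id(s): {dupes[:5]}")

    has_age = "age_years" in df.columns
    participants: list[Participant] = []
    rejections: list[Rejection] = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        pid = str(rec["participant_id"])
        label = str(rec["phenotype_label"]).strip()
        if label not in PHENOTYPE_LABELS:
            rejections.append(Rejection(pid, f"invalid phenotype_label: {label!r}"))
            continue
        age: float | None = None
        if has_age:
            raw_age = rec.get("age_years")
            if raw_age is None or (isinstance(raw_age, float) and math.isnan(raw_age)):
                rejections.append(Rejection(pid, "age missing"))
                continue
            age = float(raw_age)
            if age <= min_age:
                rejections.append(Rejection(pid, f"age ≤ {min_age:g}"))
                continue
        flags = _parse_flags(rec.get("exclusion_flags"))
        if flags:
            rejections.append(
                Rejection(pid, "exclusion flag: " + ";".join(sorted(flags)))
            )
            continue
        participants.append(
            Participant(
                participant_id=pid,
                phenotype_label=label,
                age_years=age,
                sex_at_birth=_opt_str(rec.get("sex_at_birth")),
                gender=_opt_str(rec.get("gender")),
                ancestry=_opt_str(rec.get("ancestry")),
                exclusion_flags=frozenset(),
            )
        )
    if rejections:
        logger.info("cohort %s: rejected %d of %d rows", name, len(rejections), len(df))
    return CohortDesign(
        name=name,
        phenotyping_mode=phenotyping_mode,
        maf_mode=maf_mode,
        participants=participants,
        rejection_log=rejections,
    )


def _gender_matches(
    p: Participant, synonyms: Mapping[str, str] | None
) -> tuple[bool, str | None]:
    if p.sex_at_birth not in ("Male", "Female"):
        return False, f"sex_at_birth not Male/Female: {p.sex_at_birth!r}"
    if p.gender is None:
        return False, "gender missing"
    if synonyms is None:
        # Strict rule: recorded gender must equal sex at birth exactly.
        if p.gender == p.sex_at_birth:
            return True, None
        return False, f"gender {p.gender!r} does not match sex {p.sex_at_birth!r}"
    mapped = synonyms.get(p.gender.strip().lower(), p.gender.strip())
    if mapped.lower() == p.sex_at_birth.lower():
        return True, None
    return False, f"gender {p.gender!r} does not match sex {p.sex_at_birth!r}"


def apply_sex_exclusion(
    cohort: CohortDesign, *, synonyms: Mapping[str, str] | None = None
) -> CohortDesign:
    """Restrict a cohort to sex-consistent participants.

    Retains participants whose sex at birth is "Male" or "Female" and whose
    recorded gender matches it; everyone else is excluded and logged.  The
    input cohort is untouched, so all-participant analyses still see the
    full cohort.  Pass ``synonyms=DEFAULT_GENDER_SYNONYMS`` to accept e.g.
    "Man" for "Male" case-insensitively; the default is strict equality.
    """
    retained: list[Participant] = []
    excluded: list[Rejection] = []
    for p in cohort.participants:
        ok, reason = _gender_matches(p, synonyms)
        if ok:
            retained.append(p)
        else:
            excluded.append(Rejection(p.participant_id, reason or "sex mismatch"))
    if excluded:
        logger.info(
            "cohort %s: %d participants excluded from sex-specific analyses",
            cohort.name,
            len(excluded),
        )
    return CohortDesign(
        name=f"{cohort.name}[sex-consistent]",
        phenotyping_mode=cohort.phenotyping_mode,
        maf_mode=cohort.maf_mode,
        participants=retained,
        rejection_log=excluded,
    )


def stratify(
    cohort: CohortDesign,
    by: Iterable[str] = (),
    *,
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
    synonyms: Mapping[str, str] | None = None,
) -> list[Stratum]:
    """Partition a cohort by sex and/or ancestry.

    ``by`` is a subset of {"sex", "ancestry"}.  When it contains "sex" the
    sex-consistency exclusion is applied first, so strata partition the
    sex-filtered cohort.  A stratum whose normal or impaired group is
    smaller than ``min_stratum_size`` is returned with ``skipped=True``
    rather than analysed.
    """
    by = set(by)
    unknown = by - {"sex", "ancestry"}
    if unknown:
        raise UsageError(f"unknown stratification variable(s): {sorted(unknown)}")

    base = apply_sex_exclusion(cohort, synonyms=synonyms) if "sex" in by else cohort
    if not by:
        groups: dict[str, list[Participant]] = {"all": list(base.participants)}
    else:
        groups = {}
        for p in base.participants:
            parts = []
            if "sex" in by:
                parts.append(p.sex_at_birth or "Unknown")
            if "ancestry" in by:
                parts.append(p.ancestry or "Unknown")
            groups.setdefault("/".join(parts), []).append(p)

    strata: list[Stratum] = []
    for label in sorted(groups):
        members = groups[label]
        sub = CohortDesign(
            name=f"{cohort.name}[{label}]",
            phenotyping_mode=cohort.phenotyping_mode,
            maf_mode=cohort.maf_mode,
            participants=members,
        )
        n_normal = sum(1 for p in members if p.phenotype_label == "normal")
        n_impaired = sum(1 for p in members if p.phenotype_label == "impaired")
        if min(n_normal, n_impaired) < min_stratum_size:
            strata.append(
                Stratum(
                    label,
                    sub,
                    skipped=True,
                    skip_reason="skipped: insufficient participants",
                )
            )
        else:
            strata.append(Stratum(label, sub))
    return strata


def summarize(cohort: CohortDesign) -> CohortSummary:
    """Count the phenotype groups with a per-sex breakdown and integer
    half-up-rounded percentages of classified participants."""
    n_normal = n_impaired = n_unknown = 0
    normal_by_sex: dict[str, int] = {}
    impaired_by_sex: dict[str, int] = {}
    for p in cohort.participants:
        sex = p.sex_at_birth or "Unknown"
        if p.phenotype_label == "normal":
            n_normal += 1
            normal_by_sex[sex] = normal_by_sex.get(sex, 0) + 1
        elif p.phenotype_label == "impaired":
            n_impaired += 1
            impaired_by_sex[sex] = impaired_by_sex.get(sex, 0) + 1
        else:
            n_unknown += 1
    classified = n_normal + n_impaired
    if classified == 0:
        logger.warning("cohort %s has no classified participants", cohort.name)
        pct_normal = pct_impaired = None
    else:
        pct_normal = round_half_up(100.0 * n_normal / classified)
        pct_impaired = round_half_up(100.0 * n_impaired / classified)
    return CohortSummary(
        total_participants=len(cohort.participants),
        total_classified=classified,
        n_normal=n_normal,
        n_impaired=n_impaired,
        n_unknown=n_unknown,
        normal_by_sex=normal_by_sex,
        impaired_by_sex=impaired_by_sex,
        pct_normal=pct_normal,
        pct_impaired=pct_impaired,
    )


def cohort_from_counts(
    name: str,
    *,
    normal_by_sex: Mapping[str, int],
    impaired_by_sex: Mapping[str, int],
    phenotyping_mode: str = "self_report",
) -> CohortDesign:
    """Construct a cohort with the given group-by-sex counts.

    Useful for reproducing published cohort summaries, where only the
    marginal counts are available.
    """
    participants: list[Participant] = []
    i = 0
    for label, by_sex in (("normal", normal_by_sex), ("impaired", impaired_by_sex)):
        for sex, count in by_sex.items():
            for _ in range(int(count)):
                participants.append(
                    Participant(
                        participant_id=f"{name}-{i:07d}",
                        phenotype_label=label,
                        sex_at_birth=sex,
                        gender=sex,
                    )
                )
                i += 1
    return CohortDesign(name=name, phenotyping_mode=phenotyping_mode, participants=participants)
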