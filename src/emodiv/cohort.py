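"""Domain types and tabular I/O for CHR/HC cohort data.

A cohort row holds one participant: group label (``CHR`` = clinical
high-risk syndrome, ``HC`` = healthy control), demographics, a current
antipsychotic-use flag, the 18 mDES emotion ratings and the eleven SIPS
(Structured Interview for Psychosis-Risk Syndromes) symptom severities
P1-P5 and N1-N6, each rated 0-6.

CSV layout (header required, UTF-8): ``id, group, age, sex,
parent_education, antipsychotic`` followed by the 18 emotion columns in
canonical order and ``P1..P5, N1..N6``. Booleans are serialized as 0/1.
``parent_education`` is optional on input.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .items import ALL_ITEMS, NEGATIVE_ITEMS, POSITIVE_ITEMS

logger = logging.getLogger("emodiv")

GROUPS = ("CHR", "HC")
SEXES = ("male", "female")
POSITIVE_SYMPTOMS: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5")
NEGATIVE_SYMPTOMS: tuple[str, ...] = ("N1", "N2", "N3", "N4", "N5", "N6")
ALL_SYMPTOMS: tuple[str, ...] = POSITIVE_SYMPTOMS + NEGATIVE_SYMPTOMS

#: Deterministic column order for every cohort table this package writes.
COHORT_COLUMNS: tuple[str, ...] = (
    ("id", "group", "age", "sex", "parent_education", "antipsychotic")
    + ALL_ITEMS
    + ALL_SYMPTOMS
)

REQUIRED_COLUMNS: tuple[str, ...] = tuple(
    c for c in COHORT_COLUMNS if c != "parent_education"
)

#: Maximum severity of a single SIPS item.
SIPS_MAX = 6

# HC participants with a total attenuated positive score at or above this
# are flagged (an HC by definition carries little attenuated symptomatology).
HC_POSITIVE_FLAG_THRESHOLD = 3


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class CohortValidationError(ValueError):
    """A row violates the cohort schema (bad rating, duplicate id, ...)."""


@dataclass(frozen=True)
class MdesRatings:
    """One participant's 18 emotion ratings, item name -> integer 0-4."""

    ratings: dict[str, int]

    def validate(self) -> None:
        missing = [i for i in ALL_ITEMS if i not in self.ratings]
        if missing:
            raise CohortValidationError(f"missing emotion ratings: {missing}")
        for item in ALL_ITEMS:
            r = self.ratings[item]
            if r not in (0, 1, 2, 3, 4):
                raise CohortValidationError(
                    f"rating for {item!r} must be an integer in 0..4, got {r!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.ratings[i] for i in ALL_ITEMS], dtype=float)


@dataclass(frozen=True)
class SipsScores:
    """SIPS severities P1-P5 and N1-N6, each 0-6; totals are derived."""

    scores: dict[str, int]

    def validate(self) -> None:
        missing = [s for s in ALL_SYMPTOMS if s not in self.scores]
        if missing:
            raise CohortValidationError(f"missing SIPS scores: {missing}")
        for sym in ALL_SYMPTOMS:
            v = self.scores[sym]
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= SIPS_MAX):
                raise CohortValidationError(
                    f"SIPS {sym} must be an integer in 0..{SIPS_MAX}, got {v!r}"
                )

    @property
    def total_positive(self) -> int:
        return int(sum(self.scores[s] for s in POSITIVE_SYMPTOMS))

    @property
    def total_negative(self) -> int:
        return int(sum(self.scores[s] for s in NEGATIVE_SYMPTOMS))


@dataclass(frozen=True)
class Participant:
    id: str
    group: str  # "CHR" | "HC"
    age: float
    sex: str  # "male" | "female"
    antipsychotic: bool
    mdes: MdesRatings
    sips: SipsScores
    parent_education: float | None = None

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise CohortValidationError(
                f"participant {self.id}: group must be CHR or HC, got {self.group!r}"
            )
        if self.sex not in SEXES:
            raise CohortValidationError(
                f"participant {self.id}: sex must be male or female, got {self.sex!r}"
            )
        self.mdes.validate()
        self.sips.validate()


@dataclass
class Cohort:
    """An ordered collection of participants with unique ids."""

    participants: list[Participant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)

    def validate(self) -> None:
        ids = [p.id for p in self.participants]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise CohortValidationError(f"duplicate participant ids: {dupes}")
        for p in self.participants:
            p.validate()

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame in the canonical column order."""
        rows = []
        for p in self.participants:
            row: dict[str, object] = {
                "id": p.id,
                "group": p.group,
                "age": p.age,
                "sex": p.sex,
                "parent_education": (
                    np.nan if p.parent_education is None else p.parent_education
                ),
                "antipsychotic": int(p.antipsychotic),
            }
            row.update({i: p.mdes.ratings[i] for i in ALL_ITEMS})
            row.update({s: p.sips.scores[s] for s in ALL_SYMPTOMS})
            rows.append(row)
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, strict: bool = True) -> "Cohort":
        """Build a validated Cohort from a DataFrame.

        In non-strict mode, rows failing validation (and later duplicates of
        an already-seen id) are dropped with a logged warning; in strict mode
        the first violation raises.
        """
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        has_pe = "parent_education" in frame.columns
        participants: list[Participant] = []
        seen: set[str] = set()
        n_dropped = 0
        for _, rec in frame.iterrows():
            try:
                pid = str(rec["id"])
                if pid in seen:
                    raise CohortValidationError(f"duplicate participant id: {pid}")
                pe = None
                if has_pe and pd.notna(rec["parent_education"]):
                    pe = float(rec["parent_education"])
                p = Participant(
                    id=pid,
                    group=str(rec["group"]),
                    age=float(rec["age"]),
                    sex=str(rec["sex"]),
                    parent_education=pe,
                    antipsychotic=_parse_bool(rec["antipsychotic"], pid),
                    mdes=MdesRatings(
                        {i: _parse_int(rec[i], i, pid) for i in ALL_ITEMS}
                    ),
                    sips=SipsScores(
                        {s: _parse_int(rec[s], s, pid) for s in ALL_SYMPTOMS}
                    ),
                )
                p.validate()
            except (CohortValidationError, ValueError, TypeError) as exc:
                if strict:
                    if isinstance(exc, CohortValidationError):
                        raise
                    raise CohortValidationError(str(exc)) from exc
                n_dropped += 1
                logger.warning("dropping invalid row (id=%r): %s", rec.get("id"), exc)
                continue
            seen.add(pid)
            participants.append(p)
        if n_dropped:
            logger.warning("excluded %d invalid row(s) from cohort", n_dropped)
        return cls(participants)


def _parse_bool(value: object, pid: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    if isinstance(value, float) and value in (0.0, 1.0):
        return bool(value)
    if isinstance(value, str) and value.strip() in ("0", "1"):
        return value.strip() == "1"
    raise CohortValidationError(
        f"participant {pid}: antipsychotic flag must be 0/1, got {value!r}"
    )


def _parse_int(value: object, column: str, pid: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise CohortValidationError(
            f"participant {pid}: {column} is not numeric: {value!r}"
        )
    if not float(f).is_integer():
        raise CohortValidationError(
            f"participant {pid}: {column} must be an integer, got {value!r}"
        )
    return int(f)


def read_cohort_csv(path: str | Path, strict: bool = False) -> Cohort:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file with the canonical header.
    strict
        If True, any invalid row raises :class:`CohortValidationError`;
        otherwise invalid rows are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    frame.columns = [str(c).strip() for c in frame.columns]
    return Cohort.from_frame(frame, strict=strict)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV in the deterministic canonical column order."""
    cohort.validate()
    path = Path(path)
    frame = cohort.to_frame()
    frame.to_csv(path, index=False)
    return path


@dataclass
class ValidationReport:
    """Rule-keyed tallies of cohort problems; never mutates its input."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    def error_counts(self) -> Counter:
        return Counter(rule for rule, _ in self.errors)

    def warning_counts(self) -> Counter:
        return Counter(rule for rule, _ in self.warnings)

    @property
    def n_errors(self) -> int:
        return len(self.errors)

    @property
    def n_warnings(self) -> int:
        return len(self.warnings)


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Report rule violations (duplicate ids, out-of-range scores, flagged
    HC symptom elevations) without raising or mutating."""
    report = ValidationReport()
    ids = [p.id for p in cohort.participants]
    for pid, count in Counter(ids).items():
        if count > 1:
            report.errors.append(
                ("duplicate_id", f"id {pid!r} appears {count} times")
            )
    for p in cohort.participants:
        if p.group not in GROUPS:
            report.errors.append(("bad_group", f"{p.id}: {p.group!r}"))
        if p.sex not in SEXES:
            report.errors.append(("bad_sex", f"{p.id}: {p.sex!r}"))
        for item in ALL_ITEMS:
            r = p.mdes.ratings.get(item)
            if r not in (0, 1, 2, 3, 4):
                report.errors.append(
                    ("rating_range", f"{p.id}: {item}={r!r}")
                )
        for sym in ALL_SYMPTOMS:
            v = p.sips.scores.get(sym)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= SIPS_MAX):
                report.errors.append(("sips_range", f"{p.id}: {sym}={v!r}"))
        if (
            p.group == "HC"
            and all(s in p.sips.scores for s in POSITIVE_SYMPTOMS)
            and p.sips.total_positive >= HC_POSITIVE_FLAG_THRESHOLD
        ):
            report.warnings.append(
                (
                    "hc_symptom_elevation",
                    f"{p.id}: HC with total positive symptoms "
                    f"{p.sips.total_positive}",
                )
            )
    for rule, detail in report.errors:
        logger.warning("validation error [%s]: %s", rule, detail)
    for rule, detail in report.warnings:
        logger.info("validation warning [%s]: %s", rule, detail)
    return report


def group_sizes(cohort: Cohort | pd.DataFrame) -> dict[str, int]:
    frame = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    return frame["group"].value_counts().to_dict()


def cohort_from_arrays(
    ids: Iterable[str],
    group: Iterable[str],
    age: Iterable[float],
    sex: Iterable[str],
    parent_education: Iterable[float],
    antipsychotic: Iterable[int],
    ratings: np.ndarray,
    sips: np.ndarray,
) -> Cohort:
    """Assemble a Cohort from column arrays (ratings: n x 18, sips: n x 11)."""
    participants = []
    for k, pid in enumerate(ids):
        participants.append(
            Participant(
                id=str(pid),
                group=list(group)[k] if not isinstance(group, (list, np.ndarray)) else group[k],
                age=float(np.asarray(age)[k]),
                sex=sex[k],
                parent_education=float(np.asarray(parent_education)[k]),
                antipsychotic=bool(np.asarray(antipsychotic)[k]),
                mdes=MdesRatings(
                    {item: int(ratings[k, j]) for j, item in enumerate(ALL_ITEMS)}
                ),
                sips=SipsScores(
                    {sym: int(sips[k, j]) for j, sym in enumerate(ALL_SYMPTOMS)}
                ),
            )
        )
    return Cohort(participants)
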