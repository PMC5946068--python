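"""Cause-of-death taxonomy, death records, record filtering and age-bin handling.

Every death carries a two-axis cause-of-death classification: a
*pathophysiological process* (PP) — the mechanism of disease — and an
*organ system* (OS) — the anatomical system primarily affected.  Both axes
admit an ``unclassified`` label for diagnoses too vague to place.  Records
whose cause is unclassified on either axis, and records whose only diagnosis
is euthanasia, are excluded from morbidity and comparison analyses.

Veterinary registry data often record age only as a bin ("10-15 years");
:class:`AgeBinScheme` maps bins to representative midpoint ages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PP_CATEGORIES",
    "OS_CATEGORIES",
    "UNCLASSIFIED",
    "EUTHANASIA",
    "CauseTaxonomy",
    "DeathRecord",
    "AgeBin",
    "AgeBinScheme",
    "FilterReport",
    "classify_record",
    "filter_records",
    "assign_bin_midpoint",
    "normalize_diagnosis",
]

#: Pathophysiological-process axis (mechanism of disease).
PP_CATEGORIES: tuple[str, ...] = (
    "congenital",
    "degenerative",
    "infectious",
    "inflammatory",
    "metabolic",
    "neoplastic",
    "toxic",
    "traumatic",
    "vascular",
)

#: Organ-system axis (anatomical system primarily affected).
OS_CATEGORIES: tuple[str, ...] = (
    "cardiovascular",
    "dermatologic",
    "endocrine",
    "gastrointestinal",
    "hematopoietic",
    "hepatic",
    "musculoskeletal",
    "neurologic",
    "ophthalmologic",
    "respiratory",
    "urogenital",
)

UNCLASSIFIED = "unclassified"
EUTHANASIA = "euthanasia"


def normalize_diagnosis(s: str) -> str:
    """Case-insensitive, whitespace-normalized form of a diagnosis string."""
    return " ".join(s.strip().lower().split())


class InvalidRecordError(ValueError):
    """A death record violates a structural invariant."""


class UnknownBinError(KeyError):
    """An age interval does not match any bin of the scheme."""


@dataclass(frozen=True)
class CauseTaxonomy:
    """Diagnosis -> (process, organ system) lookup table.

    ``diagnosis_map`` keys are normalized diagnosis strings; values are
    ``(pp, os)`` pairs drawn from the fixed category sets (plus
    ``unclassified`` on either axis).
    """

    diagnosis_map: Mapping[str, tuple[str, str]]
    pp_categories: tuple[str, ...] = PP_CATEGORIES + (UNCLASSIFIED,)
    os_categories: tuple[str, ...] = OS_CATEGORIES + (UNCLASSIFIED,)

    def __post_init__(self) -> None:
        normed = {}
        for diag, (pp, os) in self.diagnosis_map.items():
            if pp not in self.pp_categories:
                raise ValueError(f"unknown process category {pp!r} for {diag!r}")
            if os not in self.os_categories:
                raise ValueError(f"unknown organ-system category {os!r} for {diag!r}")
            normed[normalize_diagnosis(diag)] = (pp, os)
        object.__setattr__(self, "diagnosis_map", normed)

    def lookup(self, diagnosis: str) -> tuple[str, str]:
        """Classify one diagnosis; unknown strings map to (unclassified, unclassified)."""
        return self.diagnosis_map.get(
            normalize_diagnosis(diagnosis), (UNCLASSIFIED, UNCLASSIFIED)
        )

    def diagnoses_for_pp(self, pp: str) -> list[str]:
        """All vocabulary diagnoses whose process label is ``pp``."""
        return [d for d, (p, _) in self.diagnosis_map.items() if p == pp]

    @classmethod
    def from_csv(cls, path: str | Path) -> "CauseTaxonomy":
        """Read a ``diagnosis,pp,os`` table."""
        mapping: dict[str, tuple[str, str]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                mapping[row["diagnosis"]] = (row["pp"].strip(), row["os"].strip())
        return cls(diagnosis_map=mapping)

    @classmethod
    def default(cls) -> "CauseTaxonomy":
        """The packaged default vocabulary (covers the synthetic generator)."""
        ref = resources.files("dogyears.data") / "default_taxonomy.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass
class DeathRecord:
    """One individual's death (or censoring) record.

    Exactly one of ``age_years`` / ``age_interval`` is set.  Deaths carry at
    least one diagnosis, a pre-assigned primary diagnosis, and a (pp, os)
    cause classification; censored records carry no cause labels.
    """

    id: str
    cohort: str
    sex: str  # "female" | "male"
    age_years: float | None = None
    age_interval: tuple[float, float] | None = None
    diagnoses: list[str] = field(default_factory=list)
    primary_diagnosis: str | None = None
    cause_pp: str | None = None
    cause_os: str | None = None
    event: str = "death"  # "death" | "censored"

    def __post_init__(self) -> None:
        if (self.age_years is None) == (self.age_interval is None):
            raise InvalidRecordError(
                f"record {self.id}: exactly one of age_years/age_interval required"
            )
        if self.age_years is not None and self.age_years < 0:
            raise InvalidRecordError(f"record {self.id}: negative age")
        if self.age_interval is not None:
            lo, hi = self.age_interval
            if not lo < hi:
                raise InvalidRecordError(f"record {self.id}: interval needs lo < hi")
        if self.sex not in ("female", "male"):
            raise InvalidRecordError(f"record {self.id}: unknown sex {self.sex!r}")
        if self.event not in ("death", "censored"):
            raise InvalidRecordError(f"record {self.id}: unknown event {self.event!r}")
        if self.event == "death" and not self.diagnoses:
            raise InvalidRecordError(f"record {self.id}: death with no diagnoses")
        if self.event == "censored" and (self.cause_pp or self.cause_os):
            raise InvalidRecordError(f"record {self.id}: censored record has cause labels")

    @property
    def age(self) -> float:
        """Representative age: exact age, or the interval midpoint."""
        if self.age_years is not None:
            return self.age_years
        lo, hi = self.age_interval  # type: ignore[misc]
        return (lo + hi) / 2.0

    @property
    def is_death(self) -> bool:
        return self.event == "death"

    def n_diagnoses(self) -> int:
        """Multimorbidity: distinct diagnoses at death (duplicates collapse)."""
        return len({normalize_diagnosis(d) for d in self.diagnoses})


@dataclass(frozen=True)
class AgeBin:
    label: str
    lo: float
    hi: float | None  # None => open-ended top bin
    midpoint: float


@dataclass(frozen=True)
class AgeBinScheme:
    """Ordered, disjoint age bins with representative midpoint ages.

    The top bin may be open-ended (``hi is None``) with a fixed
    representative age rather than an arithmetic midpoint.
    """

    bins: tuple[AgeBin, ...]

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for b in self.bins:
            if b.lo < prev_hi - 1e-12:
                raise ValueError(f"bins overlap or are unordered at {b.label!r}")
            if b.hi is not None:
                if not b.lo < b.hi:
                    raise ValueError(f"bin {b.label!r} needs lo < hi")
                prev_hi = b.hi
            else:
                prev_hi = float("inf")

    def by_label(self, label: str) -> AgeBin:
        key = normalize_diagnosis(label)
        for b in self.bins:
            if normalize_diagnosis(b.label) == key:
                return b
        raise UnknownBinError(f"no bin labelled {label!r}")

    def by_interval(self, lo: float, hi: float | None) -> AgeBin:
        for b in self.bins:
            if abs(b.lo - lo) < 1e-9 and (
                (b.hi is None and hi is None)
                or (b.hi is not None and hi is not None and abs(b.hi - hi) < 1e-9)
            ):
                return b
        raise UnknownBinError(f"no bin with bounds [{lo}, {hi})")

    def bin_for_age(self, age: float) -> AgeBin:
        """The bin containing an exact age (half-open [lo, hi))."""
        for b in self.bins:
            if b.lo <= age and (b.hi is None or age < b.hi):
                return b
        raise UnknownBinError(f"age {age} outside the scheme")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AgeBinScheme":
        """Read a ``label,lo_years,hi_years,midpoint_years`` table (empty hi = open)."""
        bins = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                hi = row["hi_years"].strip()
                bins.append(
                    AgeBin(
                        label=row["label"].strip(),
                        lo=float(row["lo_years"]),
                        hi=float(hi) if hi else None,
                        midpoint=float(row["midpoint_years"]),
                    )
                )
        return cls(bins=tuple(bins))

    @classmethod
    def vmdb_default(cls) -> "AgeBinScheme":
        """The packaged veterinary-registry style bin scheme.

        The three youngest bins share the representative age 0.25 years and
        the open "over 15 years" bin is represented as 17.5 years.
        """
        ref = resources.files("dogyears.data") / "vmdb_age_bins.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def classify_record(
    diagnoses: Sequence[str], primary_diagnosis: str, taxonomy: CauseTaxonomy
) -> tuple[str, str]:
    """Classify a death by its pre-assigned primary diagnosis.

    The result depends only on the primary diagnosis (primacy is assigned
    upstream of this package); unknown diagnoses classify as
    ``(unclassified, unclassified)``.
    """
    if not diagnoses:
        raise InvalidRecordError("empty diagnoses list")
    keys = {normalize_diagnosis(d) for d in diagnoses}
    if normalize_diagnosis(primary_diagnosis) not in keys:
        raise InvalidRecordError(
            f"primary diagnosis {primary_diagnosis!r} not among the record's diagnoses"
        )
    return taxonomy.lookup(primary_diagnosis)


@dataclass
class FilterReport:
    """Counts of removed records by reason."""

    euthanasia_only: int = 0
    unclassified: int = 0

    @property
    def total_removed(self) -> int:
        return self.euthanasia_only + self.unclassified

    def as_dict(self) -> dict[str, int]:
        return {
            "euthanasia_only": self.euthanasia_only,
            "unclassified": self.unclassified,
            "total_removed": self.total_removed,
        }


def filter_records(
    records: Iterable[DeathRecord],
) -> tuple[list[DeathRecord], FilterReport]:
    """Apply the registry exclusion rules.

    Removes (i) deaths whose only diagnosis is ``euthanasia`` and (ii) deaths
    whose cause is ``unclassified`` on either axis.  A ``euthanasia``
    diagnosis inside a longer list is retained.  Censored records pass
    through.  Each removed record is counted under exactly one reason;
    idempotent by construction.
    """
    kept: list[DeathRecord] = []
    report = FilterReport()
    for rec in records:
        if not rec.is_death:
            kept.append(rec)
            continue
        normed = {normalize_diagnosis(d) for d in rec.diagnoses}
        if normed == {EUTHANASIA}:
            report.euthanasia_only += 1
            continue
        if rec.cause_pp == UNCLASSIFIED or rec.cause_os == UNCLASSIFIED:
            report.unclassified += 1
            continue
        kept.append(rec)
    return kept, report


def assign_bin_midpoint(
    age_interval: tuple[float, float | None], scheme: AgeBinScheme
) -> float:
    """Representative age for a binned record: the scheme's midpoint."""
    lo, hi = age_interval
    return scheme.by_interval(lo, hi).midpoint
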