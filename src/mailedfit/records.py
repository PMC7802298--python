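"""Program records: loading, validation, and case views.

One :class:`SystemYearRecord` describes one health system's participation
in one program year of a health-plan-run mailed FIT (fecal immunochemical
test) outreach program: how many clinics the system has, which adaptations
it layered on top of the basic centrally-coordinated mailing, how many kits
were mailed, and how many members completed any CRC screening within the
follow-up window.

The packaged dataset covers 17 health systems over the 2016 and 2017
program years (27 system-year records); it ships with the distribution and
is returned by :func:`packaged_records`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    DuplicateRecordError,
    MissingColumnError,
    NonNumericCountError,
    ScreenedExceedsMailedError,
    UndefinedRateError,
    UnknownAdaptationCodeError,
    ValidationError,
)

__all__ = [
    "Adaptation",
    "SystemYearRecord",
    "CSV_COLUMNS",
    "load_records",
    "packaged_records",
    "write_records",
    "completion_rate",
    "first_participation_view",
    "paired_view",
]


class Adaptation(enum.Enum):
    """Health-system adaptations to the basic mailed-FIT program.

    Codes follow the program's shorthand: M mailed (vs in-person) return,
    Ph phone reminders, S list scrubbing, I patient incentives, E 12-month
    visit exclusion.
    """

    MAIL_RETURN = "M"
    PHONE = "Ph"
    SCRUB = "S"
    INCENTIVE = "I"
    EXCLUSION_12MO = "E"

    @classmethod
    def from_code(cls, code: str) -> "Adaptation":
        for member in cls:
            if member.value == code:
                return member
        raise UnknownAdaptationCodeError(f"unknown adaptation code {code!r}")


CSV_COLUMNS = (
    "system_id",
    "program_year",
    "clinic_count",
    "adaptations",
    "kits_mailed",
    "screened_count",
    "fit_type",
    "prior_crc_study",
)

_COUNT_COLUMNS = ("program_year", "clinic_count", "kits_mailed", "screened_count")


@dataclass(frozen=True)
class SystemYearRecord:
    """One health system in one program year."""

    system_id: str
    program_year: int
    clinic_count: int
    adaptations: frozenset[Adaptation]
    kits_mailed: int
    screened_count: int
    fit_type: str  # "OC" (OC-Auto/OC-Light) or "OTHER"
    prior_crc_study: bool

    def __post_init__(self) -> None:
        if self.clinic_count < 1:
            raise ValidationError(
                f"{self.system_id}/{self.program_year}: clinic_count must be >= 1"
            )
        if self.kits_mailed < 0 or self.screened_count < 0:
            raise ValidationError(
                f"{self.system_id}/{self.program_year}: counts must be non-negative"
            )
        if self.screened_count > self.kits_mailed:
            raise ScreenedExceedsMailedError(
                f"{self.system_id}/{self.program_year}: screened_count "
                f"{self.screened_count} exceeds kits_mailed {self.kits_mailed}"
            )
        if self.fit_type not in ("OC", "OTHER"):
            raise ValidationError(f"fit_type must be 'OC' or 'OTHER', got {self.fit_type!r}")

    @property
    def adaptation_count(self) -> int:
        return len(self.adaptations)

    def has(self, adaptation: Adaptation) -> bool:
        return adaptation in self.adaptations

    @property
    def adaptation_codes(self) -> str:
        """Semicolon-joined codes in canonical M;Ph;S;I;E order."""
        order = list(Adaptation)
        return ";".join(a.value for a in order if a in self.adaptations)


def completion_rate(record: SystemYearRecord) -> Fraction:
    """Screening completion rate: screened members / kits mailed.

    Returned as an exact :class:`fractions.Fraction` so downstream medians
    and threshold comparisons are free of floating-point artifacts.

    Raises
    ------
    UndefinedRateError
        If no kits were mailed.
    """
    if record.kits_mailed == 0:
        raise UndefinedRateError(
            f"{record.system_id}/{record.program_year}: rate undefined (0 kits mailed)"
        )
    return Fraction(record.screened_count, record.kits_mailed)


def _parse_adaptations(cell: str) -> frozenset[Adaptation]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    return frozenset(Adaptation.from_code(code.strip()) for code in cell.split(";"))


def load_records(source: str | Path) -> list[SystemYearRecord]:
    """Load system-year records from a CSV file.

    Expected header (exact): ``system_id,program_year,clinic_count,
    adaptations,kits_mailed,screened_count,fit_type,prior_crc_study``
    with adaptations a semicolon-joined code list (e.g. ``M;Ph;S``).
    """
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise MissingColumnError(f"missing column(s): {', '.join(missing)}")

    records: list[SystemYearRecord] = []
    seen: set[tuple[str, int]] = set()
    for _, row in frame.iterrows():
        for col in _COUNT_COLUMNS:
            if not str(row[col]).strip().lstrip("-").isdigit():
                raise NonNumericCountError(
                    f"non-numeric value {row[col]!r} in column {col}"
                )
        record = SystemYearRecord(
            system_id=str(row["system_id"]).strip(),
            program_year=int(row["program_year"]),
            clinic_count=int(row["clinic_count"]),
            adaptations=_parse_adaptations(str(row["adaptations"])),
            kits_mailed=int(row["kits_mailed"]),
            screened_count=int(row["screened_count"]),
            fit_type=str(row["fit_type"]).strip(),
            prior_crc_study=str(row["prior_crc_study"]).strip() in ("1", "True", "true"),
        )
        key = (record.system_id, record.program_year)
        if key in seen:
            raise DuplicateRecordError(f"duplicate record for {key}")
        seen.add(key)
        records.append(record)
    return records


def write_records(records: Iterable[SystemYearRecord], dest: str | Path) -> None:
    """Write records back to the CSV schema (round-trips with load_records)."""
    rows = [
        {
            "system_id": r.system_id,
            "program_year": r.program_year,
            "clinic_count": r.clinic_count,
            "adaptations": r.adaptation_codes,
            "kits_mailed": r.kits_mailed,
            "screened_count": r.screened_count,
            "fit_type": r.fit_type,
            "prior_crc_study": int(r.prior_crc_study),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(dest, index=False)


def packaged_records() -> list[SystemYearRecord]:
    """The packaged 27 system-year records (17 systems, 2016-2017)."""
    with resources.as_file(
        resources.files("mailedfit.data").joinpath("program_records.csv")
    ) as path:
        return load_records(path)


def first_participation_view(records: Sequence[SystemYearRecord]) -> list[SystemYearRecord]:
    """Each system's earliest participation year: one case per system.

    This is the case base for the year-1 configurational analysis: systems
    that joined the program in its second year contribute their first
    (2017) record, so the packaged data yield 17 cases.
    """
    if not records:
        raise ValidationError("first_participation_view requires a non-empty collection")
    best: dict[str, SystemYearRecord] = {}
    for record in records:
        current = best.get(record.system_id)
        if current is None or record.program_year < current.program_year:
            best[record.system_id] = record
    return sorted(best.values(), key=_sort_key)


def paired_view(
    records: Sequence[SystemYearRecord],
) -> list[tuple[SystemYearRecord, SystemYearRecord]]:
    """(2016 record, 2017 record) pairs for systems present in both years."""
    by_system: dict[str, dict[int, SystemYearRecord]] = {}
    for record in records:
        by_system.setdefault(record.system_id, {})[record.program_year] = record
    pairs = [
        (years[2016], years[2017])
        for years in by_system.values()
        if 2016 in years and 2017 in years
    ]
    return sorted(pairs, key=lambda pair: _sort_key(pair[0]))


def _sort_key(record: SystemYearRecord) -> tuple[int, str]:
    sid = record.system_id
    digits = "".join(ch for ch in sid if ch.isdigit())
    return (int(digits) if digits else 0, sid)
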