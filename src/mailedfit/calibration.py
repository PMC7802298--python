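"""Outcome dichotomization and condition-table encoding.

The configurational analyses work on a *condition table*: one row per
case (health system), categorical factor columns, and a binary outcome.
The continuous screening completion rate is dichotomized at a threshold
chosen at a tertile boundary — cases in the upper two tertiles of the
rate distribution are coded as implementation successes, cases in the
lowest tertile as non-successes. On the packaged data the boundary
interval contains 19%, which is the program's headline success cutoff.

Factor codings map record fields to categorical factor levels. The
default coding has 8 factors: the five adaptation indicators, a
three-level system-size category, FIT test type, and prior-research
participation. A derived binary ``multi_clinic`` factor is available for
codings that contrast single-clinic against multi-clinic systems.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import pandas as pd

from .errors import CodingError, DegenerateCalibrationError
from .records import Adaptation, SystemYearRecord, completion_rate
from .utils import exact_fraction

__all__ = [
    "ThresholdRule",
    "Comparison",
    "CalibrationSpec",
    "TertileSplit",
    "tertile_threshold",
    "dichotomize_outcome",
    "Factor",
    "FactorCoding",
    "default_coding",
    "with_multi_clinic",
    "ConditionTable",
    "encode_condition_table",
    "case_labels",
]


class ThresholdRule(enum.Enum):
    FIXED = "fixed"
    TERTILE = "tertile"


class Comparison(enum.Enum):
    GEQ = ">="
    GT = ">"


@dataclass(frozen=True)
class CalibrationSpec:
    """How the continuous completion rate becomes a binary outcome.

    The default reproduces the program analysis: a fixed 19% cutoff,
    success when the rate is greater than or equal to the cutoff (a
    system printing exactly 19.0% counts as a success).
    """

    outcome_threshold: Fraction = Fraction(19, 100)
    threshold_rule: ThresholdRule = ThresholdRule.FIXED
    comparison: Comparison = Comparison.GEQ

    def __post_init__(self) -> None:
        thr = exact_fraction(self.outcome_threshold)
        object.__setattr__(self, "outcome_threshold", thr)
        if not (0 < thr < 1):
            raise ValueError("outcome_threshold must lie strictly between 0 and 1")


@dataclass(frozen=True)
class TertileSplit:
    """Boundary interval (lower, upper] between lowest and upper tertiles."""

    lower: Fraction
    upper: Fraction
    n_low: int
    n_high: int

    def contains(self, value: Fraction | float) -> bool:
        return self.lower < exact_fraction(value) <= self.upper


def tertile_threshold(values: Sequence[Fraction | float]) -> TertileSplit:
    """Lowest-tertile vs upper-two-tertiles boundary of a rate distribution.

    The lowest tertile holds ``n // 3`` cases, one more when ``n % 3 == 2``
    (the integer partition of n closest to thirds, ties resolved toward the
    smaller lowest tertile). Any threshold strictly inside the returned
    interval, applied as "success iff rate >= threshold", induces the same
    low/high split.

    Raises
    ------
    DegenerateCalibrationError
        Fewer than 3 distinct values, or no split with distinct boundary
        values exists near the target partition.
    """
    vals = sorted(exact_fraction(v) for v in values)
    n = len(vals)
    if n < 3 or len(set(vals)) < 3:
        raise DegenerateCalibrationError(
            "tertile calibration needs at least 3 distinct values"
        )
    target = n // 3 + (1 if n % 3 == 2 else 0)
    # Prefer the target split; on a boundary tie shift outward, smaller first.
    for delta in range(0, n):
        for n_low in (target - delta, target + delta):
            if 1 <= n_low <= n - 1 and vals[n_low - 1] < vals[n_low]:
                return TertileSplit(
                    lower=vals[n_low - 1],
                    upper=vals[n_low],
                    n_low=n_low,
                    n_high=n - n_low,
                )
    raise DegenerateCalibrationError("no tertile boundary with distinct values")


def dichotomize_outcome(
    records: Sequence[SystemYearRecord],
    spec: CalibrationSpec | None = None,
) -> tuple[list[int], Fraction]:
    """Binary success outcome per record, plus the effective threshold.

    Under the TERTILE rule the effective threshold is the smallest
    upper-two-tertiles rate (with GEQ this reproduces the tertile split
    exactly); under FIXED it is ``spec.outcome_threshold``.
    """
    spec = spec or CalibrationSpec()
    rates = [completion_rate(r) for r in records]
    if spec.threshold_rule is ThresholdRule.TERTILE:
        threshold = tertile_threshold(rates).upper
    else:
        threshold = spec.outcome_threshold
    if spec.comparison is Comparison.GEQ:
        outcomes = [int(rate >= threshold) for rate in rates]
    else:
        outcomes = [int(rate > threshold) for rate in rates]
    return outcomes, threshold


# ---------------------------------------------------------------------------
# Factor coding


@dataclass(frozen=True)
class Factor:
    """One categorical factor: a name, its levels, and an extractor."""

    name: str
    levels: tuple
    extract: Callable[[SystemYearRecord], object]

    def value_for(self, record: SystemYearRecord):
        value = self.extract(record)
        if value not in self.levels:
            raise CodingError(
                f"factor {self.name!r}: value {value!r} outside levels {self.levels}"
            )
        return value


@dataclass(frozen=True)
class FactorCoding:
    """An ordered collection of factors defining the condition-table schema."""

    factors: tuple[Factor, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def schema(self) -> dict[str, tuple]:
        return {f.name: f.levels for f in self.factors}

    def describe(self) -> dict[str, list]:
        """Echoable form of the effective coding (for reports/logs)."""
        return {f.name: list(f.levels) for f in self.factors}


def _adaptation_factor(adaptation: Adaptation) -> Factor:
    return Factor(
        name=adaptation.name,
        levels=(0, 1),
        extract=lambda r, a=adaptation: int(a in r.adaptations),
    )


def _three_level_size(record: SystemYearRecord) -> str:
    if record.clinic_count == 1:
        return "1"
    if record.clinic_count <= 4:
        return "2-4"
    return "5+"


def default_coding(size: str = "three_level") -> FactorCoding:
    """The default 8-factor coding.

    Five adaptation indicators, system size (three-level ``1 / 2-4 / 5+``
    by default, or binary single/multi with ``size="binary"``), FIT test
    type, and prior-research participation.
    """
    if size == "three_level":
        size_factor = Factor("size_category", ("1", "2-4", "5+"), _three_level_size)
    elif size == "binary":
        size_factor = Factor(
            "multi_clinic", (0, 1), lambda r: int(r.clinic_count > 1)
        )
    else:
        raise ValueError("size must be 'three_level' or 'binary'")
    factors = tuple(_adaptation_factor(a) for a in Adaptation) + (
        size_factor,
        Factor("fit_type", ("OC", "OTHER"), lambda r: r.fit_type),
        Factor("prior_crc_study", (0, 1), lambda r: int(r.prior_crc_study)),
    )
    return FactorCoding(factors)


def with_multi_clinic(coding: FactorCoding) -> FactorCoding:
    """Append the derived binary single-vs-multi-clinic factor."""
    if "multi_clinic" in coding.names:
        return coding
    extra = Factor("multi_clinic", (0, 1), lambda r: int(r.clinic_count > 1))
    return FactorCoding(coding.factors + (extra,))


# ---------------------------------------------------------------------------
# Condition table


@dataclass
class ConditionTable:
    """Cases x categorical factors plus a binary ``outcome`` column."""

    frame: pd.DataFrame  # index: case ids; columns: factors + "outcome"
    schema: dict[str, tuple]

    def __post_init__(self) -> None:
        if "outcome" not in self.frame.columns:
            raise ValueError("condition table needs an 'outcome' column")
        bad = set(self.frame["outcome"]) - {0, 1}
        if bad:
            raise ValueError(f"outcome must be binary, found {bad}")
        missing = [name for name in self.schema if name not in self.frame.columns]
        if missing:
            raise ValueError(f"schema factors missing from frame: {missing}")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, schema: Mapping[str, tuple] | None = None
    ) -> "ConditionTable":
        """Build from a DataFrame; schema inferred from observed values."""
        if schema is None:
            schema = {
                col: tuple(sorted(frame[col].unique(), key=repr))
                for col in frame.columns
                if col != "outcome"
            }
        return cls(frame=frame.copy(), schema=dict(schema))

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.schema)

    @property
    def case_ids(self) -> list:
        return list(self.frame.index)

    @property
    def n_cases(self) -> int:
        return len(self.frame)

    @property
    def positive_ids(self) -> frozenset:
        return frozenset(self.frame.index[self.frame["outcome"] == 1])

    @property
    def n_positive(self) -> int:
        return int((self.frame["outcome"] == 1).sum())


def case_labels(records: Sequence[SystemYearRecord]) -> list[str]:
    """Stable case ids: the system id, disambiguated by year if repeated."""
    ids = [r.system_id for r in records]
    if len(set(ids)) == len(ids):
        return ids
    return [f"{r.system_id}:{r.program_year}" for r in records]


def encode_condition_table(
    records: Sequence[SystemYearRecord],
    coding: FactorCoding,
    outcomes: Sequence[int],
) -> ConditionTable:
    """Encode records into a condition table under a factor coding."""
    if len(outcomes) != len(records):
        raise ValueError("outcomes must align one-to-one with records")
    rows = []
    for record, outcome in zip(records, outcomes):
        row = {factor.name: factor.value_for(record) for factor in coding.factors}
        row["outcome"] = int(outcome)
        rows.append(row)
    frame = pd.DataFrame(rows, index=case_labels(records))
    return ConditionTable(frame=frame, schema=coding.schema)
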