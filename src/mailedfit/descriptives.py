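"""Descriptive summaries and the kit-weighted regression.

Stratified medians/ranges of screening completion rates by adaptation and
system characteristic, improvement counts for two-year systems, group
means, and a weighted least-squares fit of completion rate (proportion
scale) on the number of adaptations, weighted by kits mailed. On the
proportion scale the fitted slope reads directly as "percentage points of
screening per additional adaptation" after multiplying by 100.

Medians are computed on exact rationals (mean of the middle two for even
n) and printed percentages use half-away-from-zero rounding, the
convention of the program's published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SingularDesignError, ValidationError
from .records import Adaptation, SystemYearRecord, completion_rate
from .utils import percent

__all__ = [
    "StratifiedSummary",
    "WLSFit",
    "STRATIFIERS",
    "stratified_summary",
    "weighted_regression",
    "improvement_counts",
    "group_means",
    "exact_median",
]


def exact_median(values: Sequence[Fraction]) -> Fraction:
    """Median as an exact rational; mean of the middle two for even n."""
    ordered = sorted(Fraction(v) for v in values)
    n = len(ordered)
    if n == 0:
        raise ValueError("median of empty sequence")
    mid = n // 2
    if n % 2:
        return ordered[mid]
    return (ordered[mid - 1] + ordered[mid]) / 2


@dataclass(frozen=True)
class StratifiedSummary:
    """Median and range of completion rates within one stratum."""

    stratum: str
    n: int
    median: Fraction
    minimum: Fraction
    maximum: Fraction

    @property
    def printed(self) -> str:
        """Whole-percent form matching the published table style."""
        return f"{percent(self.median)}% ({percent(self.minimum)}-{percent(self.maximum)}%)"


# Stratifier registry: name -> (record -> stratum label)
def _adaptation_stratifier(adaptation: Adaptation, present: str, absent: str):
    return lambda r: present if adaptation in r.adaptations else absent


STRATIFIERS: dict[str, Callable[[SystemYearRecord], str]] = {
    "overall": lambda r: "Rates overall",
    "n_adaptations": lambda r: {1: "One", 2: "Two", 3: "Three", 4: "Four", 5: "Five"}[
        r.adaptation_count
    ],
    "scrub": _adaptation_stratifier(Adaptation.SCRUB, "Scrubbing", "No scrubbing"),
    "phone": _adaptation_stratifier(Adaptation.PHONE, "Phone reminders", "No phone reminders"),
    "mail_return": _adaptation_stratifier(
        Adaptation.MAIL_RETURN, "Mail return allowed", "No mailed return"
    ),
    "incentive": _adaptation_stratifier(Adaptation.INCENTIVE, "Incentives", "No incentive"),
    "exclusion": _adaptation_stratifier(
        Adaptation.EXCLUSION_12MO, "12-month exclusion", "No exclusion"
    ),
    "system_size": lambda r: "Large (> 1 clinic)" if r.clinic_count > 1 else "Small",
    "fit_type": lambda r: "OC-Auto or OC-Light" if r.fit_type == "OC" else "Other",
    "prior_crc_study": lambda r: "Prior CRC study" if r.prior_crc_study else "None",
}


def stratified_summary(
    records: Sequence[SystemYearRecord],
    stratifier: str | Callable[[SystemYearRecord], str],
    year: int | None = None,
) -> list[StratifiedSummary]:
    """Median (range) of completion rates per stratum, optionally one year.

    ``stratifier`` is a registry name (see :data:`STRATIFIERS`) or any
    callable mapping a record to a stratum label. Strata are returned in
    first-appearance order of the (sorted-by-label) groups.
    """
    fn = STRATIFIERS[stratifier] if isinstance(stratifier, str) else stratifier
    selected = [r for r in records if year is None or r.program_year == year]
    groups: dict[str, list[Fraction]] = {}
    for record in selected:
        groups.setdefault(fn(record), []).append(completion_rate(record))
    return [
        StratifiedSummary(
            stratum=label,
            n=len(rates),
            median=exact_median(rates),
            minimum=min(rates),
            maximum=max(rates),
        )
        for label, rates in sorted(groups.items())
    ]


@dataclass(frozen=True)
class WLSFit:
    """Weighted least-squares fit of completion rate on adaptation count."""

    slope: float
    intercept: float
    slope_se: float
    t_statistic: float
    p_value: float
    df_resid: int
    n_obs: int
    weights: str

    def summary(self) -> str:
        return (
            "Weighted least squares: completion rate ~ adaptation count\n"
            f"  n = {self.n_obs} system-years, weights = {self.weights}\n"
            f"  slope     = {self.slope:.4f}  (SE {self.slope_se:.4f})\n"
            f"  intercept = {self.intercept:.4f}\n"
            f"  t = {self.t_statistic:.2f} on {self.df_resid} df, "
            f"two-sided p = {self.p_value:.3f}"
        )

    def plot(self, records: Sequence[SystemYearRecord], ax=None):
        """Scatter of rates vs adaptation count (marker area ~ kits mailed)
        with the fitted line overlaid. Returns the matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = [r.adaptation_count for r in records]
        y = [float(completion_rate(r)) for r in records]
        size = [r.kits_mailed / 5 for r in records]
        color = ["C0" if r.program_year == 2016 else "C1" for r in records]
        ax.scatter(x, y, s=size, c=color, alpha=0.6)
        grid = np.linspace(min(x) - 0.2, max(x) + 0.2, 50)
        ax.plot(grid, self.intercept + self.slope * grid, "k-")
        ax.set_xlabel("Number of adaptations")
        ax.set_ylabel("Completion rate")
        return ax


def weighted_regression(
    records: Sequence[SystemYearRecord],
    year: int | None = None,
) -> WLSFit:
    """WLS of completion rate (proportion) on adaptation count, kit weights.

    Pools both program years by default; pass ``year`` to restrict. The
    slope's p-value is the classical two-sided t test on n - 2 degrees
    of freedom.
    """
    selected = [r for r in records if year is None or r.program_year == year]
    if len(selected) < 3:
        raise ValidationError("weighted regression needs at least 3 records")
    weights = np.array([r.kits_mailed for r in selected], dtype=float)
    if (weights <= 0).any():
        raise ValidationError("weights (kits mailed) must be positive")
    x = np.array([r.adaptation_count for r in selected], dtype=float)
    if np.ptp(x) == 0:
        raise SingularDesignError("all adaptation counts identical; slope undefined")
    y = np.array([float(completion_rate(r)) for r in selected])
    result = sm.WLS(y, sm.add_constant(x), weights=weights).fit()
    return WLSFit(
        slope=float(result.params[1]),
        intercept=float(result.params[0]),
        slope_se=float(result.bse[1]),
        t_statistic=float(result.tvalues[1]),
        p_value=float(result.pvalues[1]),
        df_resid=int(result.df_resid),
        n_obs=len(selected),
        weights="kits_mailed",
    )


def improvement_counts(
    pairs: Sequence[tuple[SystemYearRecord, SystemYearRecord]],
) -> tuple[int, int, int]:
    """(improved, declined, unchanged) year-2 vs year-1 rate comparisons.

    Exact rational comparison; identical rates count as unchanged.
    """
    improved = declined = unchanged = 0
    for first, second in pairs:
        r1, r2 = completion_rate(first), completion_rate(second)
        if r2 > r1:
            improved += 1
        elif r2 < r1:
            declined += 1
        else:
            unchanged += 1
    return improved, declined, unchanged


_SIZE_CLASS = lambda r: "one_clinic" if r.clinic_count == 1 else "multi_clinic"
_FIT_CLASS = lambda r: r.fit_type


def group_means(
    records: Sequence[SystemYearRecord],
    measure: str,
    by: str,
) -> dict[str, float]:
    """Arithmetic group means of program measures.

    ``measure`` is one of ``adaptation_count``, ``kits_mailed`` (averaged
    over system-year observations) or ``clinic_count`` (averaged over
    distinct systems). ``by`` is ``size_class`` (one_clinic/multi_clinic)
    or ``fit_type`` (OC/OTHER).
    """
    classifier = {"size_class": _SIZE_CLASS, "fit_type": _FIT_CLASS}[by]
    if measure == "clinic_count":
        seen: dict[str, SystemYearRecord] = {}
        for record in records:
            seen.setdefault(record.system_id, record)
        units: list[SystemYearRecord] = list(seen.values())
    elif measure in ("adaptation_count", "kits_mailed"):
        units = list(records)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    groups: dict[str, list[float]] = {}
    for unit in units:
        value = getattr(unit, measure)
        groups.setdefault(classifier(unit), []).append(float(value))
    if not groups:
        raise ValidationError("no records to average")
    return {label: float(np.mean(vals)) for label, vals in sorted(groups.items())}


def summary_frame(summaries: Sequence[StratifiedSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame (CSV-ready; printed column included)."""
    return pd.DataFrame(
        {
            "stratum": [s.stratum for s in summaries],
            "n": [s.n for s in summaries],
            "median": [float(s.median) for s in summaries],
            "min": [float(s.minimum) for s in summaries],
            "max": [float(s.maximum) for s in summaries],
            "printed": [s.printed for s in summaries],
        }
    )
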