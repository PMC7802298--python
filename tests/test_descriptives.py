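from fractions import Fraction

import numpy as np
import pytest

from mailedfit.descriptives import (
    exact_median,
    group_means,
    improvement_counts,
    stratified_summary,
    weighted_regression,
)
from mailedfit.errors import SingularDesignError, ValidationError
from mailedfit.records import SystemYearRecord, paired_view


def _record(system, x_adaptations, rate_num, rate_den, year=2016, clinics=1, kits=None):
    """Record with a given adaptation count and rate, for regression tests."""
    from mailedfit.records import Adaptation

    adaptations = frozenset(list(Adaptation)[:x_adaptations])
    kits = kits if kits is not None else rate_den
    return SystemYearRecord(
        system_id=system,
        program_year=year,
        clinic_count=clinics,
        adaptations=adaptations,
        kits_mailed=kits,
        screened_count=round(kits * rate_num / rate_den),
        fit_type="OC",
        prior_crc_study=False,
    )


class TestExactMedian:
    def test_even_count_averages_middle_two(self):
        assert exact_median([Fraction(1, 4), Fraction(3, 4)]) == Fraction(1, 2)

    def test_permutation_invariance(self):
        values = [Fraction(k, 17) for k in (5, 1, 9, 3, 11)]
        assert exact_median(values) == exact_median(list(reversed(values)))
        assert exact_median(values) == Fraction(5, 17)


class TestStratifiedSummaries:
    """Printed medians/ranges match the published per-stratum cells."""

    @pytest.mark.parametrize(
        "stratifier,year,stratum,printed,n",
        [
            ("overall", 2016, "Rates overall", "20% (4-28%)", 13),
            ("overall", 2017, "Rates overall", "25% (12-35%)", 14),
            ("n_adaptations", 2016, "One", "12% (4-20%)", 4),
            ("n_adaptations", 2016, "Two", "20% (14-26%)", 5),
            ("n_adaptations", 2016, "Three", "23% (19-28%)", 4),
            ("n_adaptations", 2017, "Four", "31% (27-35%)", 2),
            ("scrub", 2016, "Scrubbing", "24% (23-28%)", 4),
            ("scrub", 2016, "No scrubbing", "15% (4-25%)", 9),
            ("scrub", 2017, "Scrubbing", "27% (12-35%)", 9),
            ("phone", 2016, "Phone reminders", "20% (14-23%)", 5),
            ("system_size", 2017, "Large (> 1 clinic)", "26% (12-35%)", 10),
            ("fit_type", 2017, "Other", "16% (12-19%)", 4),
            ("prior_crc_study", 2016, "Prior CRC study", "23% (20-26%)", 2),
        ],
    )
    def test_printed_cells(self, records, stratifier, year, stratum, printed, n):
        summaries = stratified_summary(records, stratifier, year)
        cell = next(s for s in summaries if s.stratum == stratum)
        assert cell.printed == printed
        assert cell.n == n

    def test_single_record_stratum(self, records):
        one = [r for r in records if (r.system_id, r.program_year) == ("S9", 2016)]
        (cell,) = stratified_summary(one, "overall")
        assert cell.median == cell.minimum == cell.maximum == Fraction(154, 757)

    def test_callable_stratifier(self, records):
        summaries = stratified_summary(records, lambda r: r.fit_type, 2016)
        assert {s.stratum for s in summaries} == {"OC", "OTHER"}


class TestWeightedRegression:
    def test_unit_weights_reduce_to_ordinary_least_squares(self):
        rng = np.random.default_rng(7)
        records = [
            _record(f"X{i}", x, num, 1000, kits=500)
            for i, (x, num) in enumerate(
                (int(x), int(num))
                for x, num in zip(rng.integers(1, 5, 10), rng.integers(50, 400, 10))
            )
        ]
        fit = weighted_regression(records)
        x = np.array([r.adaptation_count for r in records], dtype=float)
        y = np.array([r.screened_count / r.kits_mailed for r in records])
        slope_ols = np.polyfit(x, y, 1)[0]
        assert fit.slope == pytest.approx(slope_ols, abs=1e-12)

    def test_collinear_points_fit_exactly(self):
        records = [
            _record("X1", 1, 1, 10, kits=100),
            _record("X2", 2, 2, 10, kits=100),
            _record("X3", 3, 3, 10, kits=100),
        ]
        fit = weighted_regression(records)
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.df_resid == 1

    def test_hand_evaluated_weighted_normal_equations(self):
        # points (x, y, w): (1, 0.1, 1), (2, 0.2, 2), (3, 0.6, 1)
        # weighted means: x̄=2, ȳ=0.275; Sxy=0.5, Sxx=2 -> slope 0.25
        records = [
            _record("X1", 1, 1, 10, kits=10),
            _record("X2", 2, 2, 10, kits=20),
            _record("X3", 3, 6, 10, kits=10),
        ]
        fit = weighted_regression(records)
        assert fit.slope == pytest.approx(0.25, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.225, abs=1e-12)

    def test_pooled_packaged_fit(self, records):
        fit = weighted_regression(records)
        assert fit.n_obs == 27 and fit.df_resid == 25
        assert 0 < fit.p_value < 1

    def test_too_few_records(self, records):
        with pytest.raises(ValidationError):
            weighted_regression(records[:2])

    def test_constant_covariate_is_singular(self):
        records = [_record(f"X{i}", 2, 1, 10, kits=100) for i in range(4)]
        with pytest.raises(SingularDesignError):
            weighted_regression(records)


class TestImprovementCounts:
    def test_packaged_pairs(self, records):
        assert improvement_counts(paired_view(records)) == (7, 3, 0)

    def test_empty(self):
        assert improvement_counts([]) == (0, 0, 0)

    def test_exact_tie_counts_as_unchanged(self):
        a = _record("X", 1, 1, 10, year=2016, kits=100)
        b = _record("X", 1, 1, 10, year=2017, kits=200)
        assert improvement_counts([(a, b)]) == (0, 0, 1)


class TestGroupMeans:
    def test_adaptations_by_system_size(self, records):
        means = group_means(records, "adaptation_count", "size_class")
        assert means["one_clinic"] == pytest.approx(1.75)
        assert means["multi_clinic"] == pytest.approx(49 / 19)  # prints 2.6

    def test_kits_by_fit_type(self, records):
        means = group_means(records, "kits_mailed", "fit_type")
        assert means["OC"] == pytest.approx(7267 / 20)  # prints 363
        assert means["OTHER"] == pytest.approx(1077 / 7)  # prints 154

    def test_clinics_per_distinct_system(self, records):
        means = group_means(records, "clinic_count", "fit_type")
        assert means["OC"] == pytest.approx(41 / 12)  # prints 3.4
        assert means["OTHER"] == pytest.approx(2.0)

    def test_unknown_measure_rejected(self, records):
        with pytest.raises(ValueError):
            group_means(records, "screening_zeal", "fit_type")
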