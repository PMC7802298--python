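"""Configurational comparative engine: minimally sufficient conditions,
threshold relaxation, contradiction detection, and solution-model assembly.

The engine answers the question "which combinations of conditions
distinguish the cases with the outcome present?" in the coincidence-
analysis style:

* A **configuration** is a conjunction of factor-level literals
  (e.g. ``multi_clinic=1 & INCENTIVE=1``).
* Its **consistency** is the share of matching cases that have the
  outcome; its **coverage** is the share of outcome-positive cases it
  matches. Both are kept as exact rationals so threshold comparisons at
  values like 0.95 are free of floating-point artifacts.
* A **minimally sufficient condition** (MSC) meets a consistency
  threshold and a coverage floor while no proper sub-conjunction does.
* A **solution model** is a disjunction of MSC pathways; its metrics are
  computed on the union of matched cases (a case covered by two pathways
  counts once). Models must clear separate model-level consistency and
  coverage floors.

The search starts at 100% consistency and relaxes in 5-point steps until
configurations emerge, mirroring standard configurational practice.

The statsmodels-style front door is :class:`CoincidenceAnalysis` (the
model object, built from a :class:`~mailedfit.calibration.ConditionTable`)
whose :meth:`~CoincidenceAnalysis.fit` returns a
:class:`CoincidenceResults` carrying the ranked solution models, the MSC
list, the final threshold, and any contradictory configurations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calibration import ConditionTable
from .errors import SchemaError
from .utils import exact_fraction, round_half_away

__all__ = [
    "Configuration",
    "ConfigurationScore",
    "SearchParams",
    "SolutionModel",
    "MSCSearchResult",
    "configuration_matches",
    "score_configuration",
    "enumerate_msc",
    "relaxed_msc_search",
    "detect_contradictions",
    "assemble_models",
    "model_metrics",
    "CoincidenceAnalysis",
    "CoincidenceResults",
]


_frac = exact_fraction


@dataclass(frozen=True)
class Configuration:
    """A conjunction of factor-level literals; no factor appears twice."""

    literals: tuple[tuple[str, object], ...]

    def __post_init__(self) -> None:
        factors = [name for name, _ in self.literals]
        if len(set(factors)) != len(factors):
            raise ValueError(f"factor repeated in configuration: {factors}")
        ordered = tuple(sorted(self.literals, key=lambda lit: (lit[0], repr(lit[1]))))
        object.__setattr__(self, "literals", ordered)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "Configuration":
        return cls(tuple(mapping.items()))

    @property
    def order(self) -> int:
        return len(self.literals)

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.literals)

    def sort_key(self) -> tuple:
        return tuple((name, repr(level)) for name, level in self.literals)

    def proper_subconjunctions(self) -> Iterable["Configuration"]:
        """All non-empty conjunctions over proper subsets of the literals."""
        for k in range(1, self.order):
            for subset in itertools.combinations(self.literals, k):
                yield Configuration(subset)

    def __str__(self) -> str:
        if not self.literals:
            return "<TRUE>"
        return " & ".join(f"{name}={level}" for name, level in self.literals)


@dataclass(frozen=True)
class ConfigurationScore:
    """Consistency/coverage bookkeeping for one configuration.

    ``consistency`` is None when no case matches; ``coverage`` is None
    when the table has no positive case.
    """

    n_matched: int
    n_matched_positive: int
    n_positive_total: int
    matched_ids: frozenset
    matched_positive_ids: frozenset

    @property
    def consistency(self) -> Fraction | None:
        if self.n_matched == 0:
            return None
        return Fraction(self.n_matched_positive, self.n_matched)

    @property
    def coverage(self) -> Fraction | None:
        if self.n_positive_total == 0:
            return None
        return Fraction(self.n_matched_positive, self.n_positive_total)


@dataclass(frozen=True)
class SearchParams:
    """Thresholds governing the configurational search.

    Defaults follow standard practice for this analysis: start at 100%
    consistency with a 15% coverage floor, relax consistency in 5-point
    decrements, consider conjunctions up to order 5, and accept models
    with at least 80% consistency and 70% coverage.
    """

    initial_consistency: Fraction = Fraction(1)
    consistency_decrement: Fraction = Fraction(1, 20)
    coverage_floor: Fraction = Fraction(3, 20)
    max_order: int = 5
    model_consistency_floor: Fraction = Fraction(4, 5)
    model_coverage_floor: Fraction = Fraction(7, 10)
    max_pathways: int = 5

    def __post_init__(self) -> None:
        for name in (
            "initial_consistency",
            "consistency_decrement",
            "coverage_floor",
            "model_consistency_floor",
            "model_coverage_floor",
        ):
            object.__setattr__(self, name, _frac(getattr(self, name)))
        for name in (
            "initial_consistency",
            "coverage_floor",
            "model_consistency_floor",
            "model_coverage_floor",
        ):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.consistency_decrement <= 0:
            raise ValueError("consistency_decrement must be positive")
        if self.max_order < 1 or self.max_pathways < 1:
            raise ValueError("max_order and max_pathways must be >= 1")

    def describe(self) -> dict:
        return {
            "initial_consistency": str(self.initial_consistency),
            "consistency_decrement": str(self.consistency_decrement),
            "coverage_floor": str(self.coverage_floor),
            "max_order": self.max_order,
            "model_consistency_floor": str(self.model_consistency_floor),
            "model_coverage_floor": str(self.model_coverage_floor),
            "max_pathways": self.max_pathways,
        }


@dataclass(frozen=True)
class ScoredConfiguration:
    configuration: Configuration
    score: ConfigurationScore


@dataclass(frozen=True)
class SolutionModel:
    """A disjunction of solution pathways with union-based metrics."""

    pathways: tuple[Configuration, ...]
    consistency: Fraction
    coverage: Fraction
    n_matched: int
    n_matched_positive: int
    covered_positive_ids: tuple
    uncovered_positive_ids: tuple
    consistency_threshold: Fraction | None = None

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def sort_key(self) -> tuple:
        return (
            -self.consistency,
            -self.coverage,
            len(self.pathways),
            tuple(p.sort_key() for p in self.pathways),
        )

    def __str__(self) -> str:
        paths = " | ".join(f"({p})" for p in self.pathways)
        n_pos = len(self.covered_positive_ids) + len(self.uncovered_positive_ids)
        return (
            f"{paths}  [consistency {self.n_matched_positive}/{self.n_matched}, "
            f"coverage {self.n_matched_positive}/{n_pos}]"
        )


@dataclass(frozen=True)
class MSCSearchResult:
    """Outcome of the iterative threshold-relaxation MSC search."""

    mscs: tuple[ScoredConfiguration, ...]
    final_threshold: Fraction | None
    thresholds_tried: tuple[Fraction, ...]

    @property
    def no_solution(self) -> bool:
        return not self.mscs


# ---------------------------------------------------------------------------
# Core operations


def _check_schema(config: Configuration, table: ConditionTable) -> None:
    unknown = [name for name in config.factors if name not in table.schema]
    if unknown:
        raise SchemaError(f"configuration references unknown factor(s): {unknown}")


def configuration_matches(config: Configuration, case: Mapping[str, object]) -> bool:
    """True iff every literal's required level equals the case's value."""
    for name, level in config.literals:
        if name not in case:
            raise SchemaError(f"case lacks factor {name!r}")
        if case[name] != level:
            return False
    return True


def _matched_ids(config: Configuration, table: ConditionTable) -> frozenset:
    mask = pd.Series(True, index=table.frame.index)
    for name, level in config.literals:
        mask &= table.frame[name] == level
    return frozenset(table.frame.index[mask])


def score_configuration(config: Configuration, table: ConditionTable) -> ConfigurationScore:
    """Exact consistency/coverage of one configuration on a table."""
    _check_schema(config, table)
    if table.n_cases == 0:
        raise ValueError("cannot score against an empty table")
    matched = _matched_ids(config, table)
    positives = table.positive_ids
    matched_pos = matched & positives
    return ConfigurationScore(
        n_matched=len(matched),
        n_matched_positive=len(matched_pos),
        n_positive_total=len(positives),
        matched_ids=matched,
        matched_positive_ids=matched_pos,
    )


def _all_literals(table: ConditionTable) -> list[tuple[str, object]]:
    return [
        (name, level)
        for name in sorted(table.schema)
        for level in table.schema[name]
    ]


def enumerate_msc(
    table: ConditionTable,
    consistency_threshold: Fraction | float,
    coverage_floor: Fraction | float,
    max_order: int,
) -> list[ScoredConfiguration]:
    """All minimally sufficient conditions at the given thresholds.

    A configuration qualifies when its consistency meets the threshold
    and its coverage meets the floor; it is *minimal* when no proper
    sub-conjunction also qualifies. Output is sorted by (order ascending,
    coverage descending, lexical literal order). A table with no positive
    case has no sufficient condition: the result is empty.
    """
    if table.n_positive == 0:
        return []
    threshold = _frac(consistency_threshold)
    floor = _frac(coverage_floor)

    literal_sets = {
        lit: _matched_ids(Configuration((lit,)), table) for lit in _all_literals(table)
    }
    positives = table.positive_ids
    n_pos = len(positives)
    all_ids = frozenset(table.frame.index)

    qualifying: dict[frozenset, ScoredConfiguration] = {}
    for k in range(1, max_order + 1):
        for combo in itertools.combinations(literal_sets, k):
            factors = [name for name, _ in combo]
            if len(set(factors)) != k:
                continue
            matched = all_ids
            for lit in combo:
                matched = matched & literal_sets[lit]
                if not matched:
                    break
            if not matched:
                continue
            matched_pos = matched & positives
            if Fraction(len(matched_pos), len(matched)) < threshold:
                continue
            if Fraction(len(matched_pos), n_pos) < floor:
                continue
            config = Configuration(tuple(combo))
            qualifying[frozenset(combo)] = ScoredConfiguration(
                config,
                ConfigurationScore(
                    n_matched=len(matched),
                    n_matched_positive=len(matched_pos),
                    n_positive_total=n_pos,
                    matched_ids=matched,
                    matched_positive_ids=matched_pos,
                ),
            )

    minimal = [
        scored
        for key, scored in qualifying.items()
        if not any(
            frozenset(sub) in qualifying
            for k in range(1, len(key))
            for sub in itertools.combinations(key, k)
        )
    ]
    minimal.sort(
        key=lambda s: (
            s.configuration.order,
            -s.score.coverage,
            s.configuration.sort_key(),
        )
    )
    return minimal


def relaxed_msc_search(
    table: ConditionTable, params: SearchParams | None = None
) -> MSCSearchResult:
    """Enumerate MSCs, relaxing consistency stepwise until some emerge.

    Starts at ``initial_consistency`` and lowers the threshold by
    ``consistency_decrement`` until the MSC list is non-empty or the
    threshold would fall below ``model_consistency_floor``. An empty
    result (``no_solution``) is a reportable outcome, not an exception.
    """
    params = params or SearchParams()
    tried: list[Fraction] = []
    threshold = params.initial_consistency
    while threshold >= params.model_consistency_floor:
        tried.append(threshold)
        mscs = enumerate_msc(table, threshold, params.coverage_floor, params.max_order)
        if mscs:
            return MSCSearchResult(tuple(mscs), threshold, tuple(tried))
        threshold = threshold - params.consistency_decrement
    return MSCSearchResult((), None, tuple(tried))


def detect_contradictions(table: ConditionTable) -> list[list]:
    """Groups of cases identical on all factors but with mixed outcomes.

    Such cases can never all be covered by a 100%-consistent pathway;
    they are reported alongside models rather than silently dropped.
    """
    factors = list(table.factor_names)
    if not factors:
        return []
    groups: list[list] = []
    for _, sub in table.frame.groupby(factors, sort=True):
        if len(sub) > 1 and sub["outcome"].nunique() > 1:
            groups.append(sorted(sub.index, key=repr))
    groups.sort(key=repr)
    return groups


def _build_model(
    pathways: Sequence[ScoredConfiguration],
    table: ConditionTable,
    threshold: Fraction | None = None,
) -> SolutionModel:
    matched: frozenset = frozenset()
    matched_pos: frozenset = frozenset()
    for scored in pathways:
        matched |= scored.score.matched_ids
        matched_pos |= scored.score.matched_positive_ids
    positives = table.positive_ids
    configs = tuple(sorted((s.configuration for s in pathways), key=lambda c: c.sort_key()))
    return SolutionModel(
        pathways=configs,
        consistency=Fraction(len(matched_pos), len(matched)),
        coverage=Fraction(len(matched_pos), len(positives)),
        n_matched=len(matched),
        n_matched_positive=len(matched_pos),
        covered_positive_ids=tuple(sorted(matched_pos, key=repr)),
        uncovered_positive_ids=tuple(sorted(positives - matched_pos, key=repr)),
        consistency_threshold=threshold,
    )


def assemble_models(
    msc_list: Sequence[ScoredConfiguration],
    table: ConditionTable,
    params: SearchParams | None = None,
    threshold: Fraction | None = None,
) -> list[SolutionModel]:
    """Exhaustively assemble disjunctive solution models from MSCs.

    Considers every subset of the MSC list up to ``max_pathways``
    pathways, discards subsets containing a redundant disjunct (a pathway
    whose matched-positive set is contained in another pathway's), scores
    the rest on the union of matched cases, and keeps models clearing
    both model-level floors. The ranked list (consistency desc, coverage
    desc, fewer pathways first, lexical tie-break) is returned; an empty
    list is the no-solution signal.
    """
    if not msc_list:
        raise ValueError("assemble_models requires a non-empty MSC list")
    params = params or SearchParams()
    if table.n_positive == 0:
        raise ValueError("model assembly requires at least one positive case")

    models: list[SolutionModel] = []
    cap = min(params.max_pathways, len(msc_list))
    for size in range(1, cap + 1):
        for subset in itertools.combinations(msc_list, size):
            if _has_redundant_pathway(subset):
                continue
            model = _build_model(subset, table, threshold)
            if (
                model.consistency >= params.model_consistency_floor
                and model.coverage >= params.model_coverage_floor
            ):
                models.append(model)
    models.sort(key=SolutionModel.sort_key)
    return models


def _has_redundant_pathway(subset: Sequence[ScoredConfiguration]) -> bool:
    sets = [s.score.matched_positive_ids for s in subset]
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            if i != j and a <= b:
                return True
    return False


def model_metrics(
    model: SolutionModel | Sequence[Configuration], table: ConditionTable
) -> tuple[Fraction, Fraction, frozenset, frozenset]:
    """Recompute union-based model metrics from scratch.

    Accepts either a :class:`SolutionModel` or a bare sequence of
    configurations (useful for scoring externally specified pathways).
    Returns (consistency, coverage, covered case ids, uncovered positive
    case ids); idempotent with the values stored on a model.
    """
    pathways = model.pathways if isinstance(model, SolutionModel) else tuple(model)
    matched: frozenset = frozenset()
    for config in pathways:
        _check_schema(config, table)
        matched |= _matched_ids(config, table)
    positives = table.positive_ids
    matched_pos = matched & positives
    if not matched:
        raise ValueError("model matches no case; metrics undefined")
    consistency = Fraction(len(matched_pos), len(matched))
    coverage = Fraction(len(matched_pos), len(positives))
    return consistency, coverage, matched, positives - matched_pos


# ---------------------------------------------------------------------------
# Model-object front door


class CoincidenceAnalysis:
    """Configurational model search on a condition table.

    Parameters
    ----------
    table:
        The cases-by-factors condition table with binary outcome.
    params:
        Search thresholds; defaults to :class:`SearchParams`.

    Examples
    --------
    >>> model = CoincidenceAnalysis(table)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, table: ConditionTable, params: SearchParams | None = None):
        self.table = table
        self.params = params or SearchParams()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        schema: Mapping[str, tuple] | None = None,
        params: SearchParams | None = None,
    ) -> "CoincidenceAnalysis":
        """Build from a DataFrame with factor columns and an ``outcome`` column."""
        return cls(ConditionTable.from_frame(frame, schema), params)

    def fit(self) -> "CoincidenceResults":
        """Run the full search: relax thresholds, enumerate MSCs, assemble models.

        The consistency threshold is relaxed past the first threshold
        that yields MSCs if those MSCs cannot be assembled into any model
        clearing both model floors; relaxation stops at the model
        consistency floor.
        """
        params = self.params
        contradictions = detect_contradictions(self.table)
        tried: list[Fraction] = []
        threshold = params.initial_consistency
        mscs: tuple[ScoredConfiguration, ...] = ()
        models: list[SolutionModel] = []
        final_threshold: Fraction | None = None
        while threshold >= params.model_consistency_floor:
            tried.append(threshold)
            found = enumerate_msc(
                self.table, threshold, params.coverage_floor, params.max_order
            )
            if found:
                candidate_models = assemble_models(found, self.table, params, threshold)
                if not mscs:  # remember the first threshold where MSCs emerged
                    mscs = tuple(found)
                    final_threshold = threshold
                if candidate_models:
                    mscs = tuple(found)
                    final_threshold = threshold
                    models = candidate_models
                    break
            threshold = threshold - params.consistency_decrement
        return CoincidenceResults(
            analysis=self,
            mscs=mscs,
            models=tuple(models),
            final_threshold=final_threshold,
            thresholds_tried=tuple(tried),
            contradictions=tuple(tuple(g) for g in contradictions),
        )


@dataclass(frozen=True)
class CoincidenceResults:
    """Fitted results of a configurational model search."""

    analysis: CoincidenceAnalysis
    mscs: tuple[ScoredConfiguration, ...]
    models: tuple[SolutionModel, ...]
    final_threshold: Fraction | None
    thresholds_tried: tuple[Fraction, ...]
    contradictions: tuple[tuple, ...]

    @property
    def table(self) -> ConditionTable:
        return self.analysis.table

    @property
    def no_solution(self) -> bool:
        return not self.models

    @property
    def top_model(self) -> SolutionModel | None:
        return self.models[0] if self.models else None

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        lines = []
        t = self.table
        lines.append("Coincidence Analysis Results")
        lines.append("=" * 64)
        lines.append(f"Cases: {t.n_cases}    Positive outcome: {t.n_positive}")
        lines.append(f"Factors: {', '.join(t.factor_names)}")
        if self.final_threshold is not None:
            lines.append(
                f"Final consistency threshold: {_pct(self.final_threshold)}"
                f" (tried {len(self.thresholds_tried)} level(s))"
            )
        if self.contradictions:
            groups = "; ".join("{" + ", ".join(map(str, g)) + "}" for g in self.contradictions)
            lines.append(f"Contradictory configurations: {groups}")
        lines.append("-" * 64)
        if self.no_solution:
            lines.append("No solution model met the consistency/coverage floors.")
        else:
            top = self.top_model
            lines.append(f"Top model ({top.n_pathways} pathway(s)):")
            for p in top.pathways:
                lines.append(f"  {p}")
            lines.append(
                f"Model consistency: {top.n_matched_positive}/{top.n_matched}"
                f" = {_pct(top.consistency)}"
            )
            n_pos = len(top.covered_positive_ids) + len(top.uncovered_positive_ids)
            lines.append(
                f"Model coverage:    {top.n_matched_positive}/{n_pos}"
                f" = {_pct(top.coverage)}"
            )
            if top.uncovered_positive_ids:
                lines.append(
                    "Uncovered positives: " + ", ".join(map(str, top.uncovered_positive_ids))
                )
            if len(self.models) > 1:
                lines.append(f"(+ {len(self.models) - 1} further qualifying model(s))")
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_report(self, coding_echo: Mapping | None = None) -> dict:
        """JSON-serializable report: pathways, exact fractions, rounded percents."""
        def model_entry(m: SolutionModel) -> dict:
            return {
                "pathways": [str(p) for p in m.pathways],
                "consistency": {
                    "fraction": f"{m.n_matched_positive}/{m.n_matched}",
                    "percent": _pct_num(m.consistency),
                },
                "coverage": {
                    "fraction": (
                        f"{m.n_matched_positive}/"
                        f"{len(m.covered_positive_ids) + len(m.uncovered_positive_ids)}"
                    ),
                    "percent": _pct_num(m.coverage),
                },
                "covered_positive_ids": [str(i) for i in m.covered_positive_ids],
                "uncovered_positive_ids": [str(i) for i in m.uncovered_positive_ids],
            }

        report = {
            "n_cases": self.table.n_cases,
            "n_positive": self.table.n_positive,
            "factors": list(self.table.factor_names),
            "params": self.analysis.params.describe(),
            "final_consistency_threshold": (
                str(self.final_threshold) if self.final_threshold is not None else None
            ),
            "mscs": [
                {
                    "configuration": str(s.configuration),
                    "consistency": _pct_num(s.score.consistency),
                    "coverage": _pct_num(s.score.coverage),
                    "n_matched": s.score.n_matched,
                }
                for s in self.mscs
            ],
            "models": [model_entry(m) for m in self.models],
            "contradictions": [[str(i) for i in g] for g in self.contradictions],
            "no_solution": self.no_solution,
        }
        if coding_echo is not None:
            report["factor_coding"] = dict(coding_echo)
        return report


def _pct(x: Fraction) -> str:
    return f"{round_half_away(100 * Fraction(x), 0):.0f}%"


def _pct_num(x: Fraction | None) -> float | None:
    if x is None:
        return None
    return float(round_half_away(100 * Fraction(x), 0))
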