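"""Synthetic condition tables with planted Boolean causal structure.

The generator emulates the substrate of the configurational analysis — a
binary cases-by-factors table with a binary outcome — from a known
ground-truth model: a disjunctive normal form (DNF) over the factors.
Factor values are drawn independently at configurable prevalences (or
laid out as an exhaustive full factorial), the outcome is the DNF's
truth value, and symmetric label noise optionally flips each outcome
independently. Because the planted DNF is known, the engine's recovery
behavior is testable end to end without any external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import ConditionTable
from .ccm import Configuration, SolutionModel
from .errors import SchemaError

__all__ = ["PlantedStructure", "generate_table", "recovery_report"]


@dataclass(frozen=True)
class PlantedStructure:
    """Ground truth for a synthetic condition table.

    Parameters
    ----------
    factor_names:
        Binary factors (levels 0/1).
    dnf:
        The planted causal model: a non-empty tuple of conjunctions,
        each a mapping factor -> required level. A case is
        outcome-positive iff it satisfies at least one conjunction.
    n_cases:
        Number of cases to draw (ignored when ``exhaustive``).
    exhaustive:
        Lay out the full 2^k factorial instead of sampling.
    noise_rate:
        Probability of flipping each case's outcome, in [0, 0.5).
    prevalence:
        P(factor = 1), a scalar for all factors or a per-factor mapping.
    pair_correlation:
        With this probability a factor copies its predecessor's value
        instead of being drawn independently (adaptations co-occur in
        real programs); 0 keeps factors independent.
    seed:
        Seed for the underlying generator; same spec + seed -> same table.
    """

    factor_names: tuple[str, ...]
    dnf: tuple[Mapping[str, int], ...]
    n_cases: int = 32
    exhaustive: bool = False
    noise_rate: float = 0.0
    prevalence: float | Mapping[str, float] = 0.5
    pair_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.factor_names:
            raise ValueError("at least one factor required")
        if not self.dnf:
            raise ValueError("planted DNF must be non-empty")
        for conj in self.dnf:
            if not conj:
                raise ValueError("empty conjunction in planted DNF")
            unknown = set(conj) - set(self.factor_names)
            if unknown:
                raise ValueError(f"DNF references unknown factor(s): {sorted(unknown)}")
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must lie in [0, 0.5)")
        if not self.exhaustive and self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        object.__setattr__(self, "dnf", tuple(dict(c) for c in self.dnf))

    def prevalence_of(self, factor: str) -> float:
        if isinstance(self.prevalence, Mapping):
            return float(self.prevalence.get(factor, 0.5))
        return float(self.prevalence)

    def evaluate(self, case: Mapping[str, int]) -> int:
        """Noise-free outcome of a case under the planted DNF."""
        return int(
            any(all(case[f] == v for f, v in conj.items()) for conj in self.dnf)
        )

    def as_pathways(self) -> tuple[Configuration, ...]:
        """The planted DNF as canonical engine configurations."""
        return tuple(
            sorted(
                (Configuration.from_mapping(c) for c in self.dnf),
                key=lambda c: c.sort_key(),
            )
        )


def generate_table(spec: PlantedStructure) -> tuple[ConditionTable, PlantedStructure]:
    """Draw a condition table from a planted structure.

    Returns the table and the ground truth (the spec itself), mirroring
    a (data, truth) split for recovery experiments.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.factor_names)
    if spec.exhaustive:
        values = np.array(list(itertools.product((0, 1), repeat=len(names))))
    else:
        columns = []
        for j, name in enumerate(names):
            draw = (rng.random(spec.n_cases) < spec.prevalence_of(name)).astype(int)
            if j > 0 and spec.pair_correlation > 0:
                copy = rng.random(spec.n_cases) < spec.pair_correlation
                draw = np.where(copy, columns[j - 1], draw)
            columns.append(draw)
        values = np.column_stack(columns)
    frame = pd.DataFrame(values, columns=names)
    frame.index = [f"case{i:03d}" for i in range(len(frame))]
    outcome = frame.apply(lambda row: spec.evaluate(row.to_dict()), axis=1)
    if spec.noise_rate > 0:
        flips = rng.random(len(frame)) < spec.noise_rate
        outcome = outcome ^ flips.astype(int)
    frame["outcome"] = outcome.astype(int)
    schema = {name: (0, 1) for name in names}
    return ConditionTable(frame=frame, schema=schema), spec


def recovery_report(
    found: SolutionModel | Sequence[Configuration] | None,
    truth: PlantedStructure,
) -> tuple[bool, float]:
    """Compare a recovered model against the planted DNF.

    Returns (exact-match flag, Jaccard index of the canonicalized
    pathway sets). ``found=None`` (no solution) scores (False, 0.0).
    """
    planted = {c.literals for c in truth.as_pathways()}
    if found is None:
        return False, 0.0
    pathways = found.pathways if isinstance(found, SolutionModel) else tuple(found)
    for config in pathways:
        unknown = set(config.factors) - set(truth.factor_names)
        if unknown:
            raise SchemaError(f"recovered model uses unknown factor(s): {sorted(unknown)}")
    recovered = {c.literals for c in pathways}
    union = planted | recovered
    jaccard = len(planted & recovered) / len(union) if union else 1.0
    return recovered == planted, jaccard
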