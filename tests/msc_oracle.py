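"""Brute-force oracle for minimally-sufficient-condition enumeration.

Independent of the package's engine: tests every conjunction over the
schema directly against the table rows, then checks minimality by
re-testing every proper sub-conjunction. Only suitable for tiny tables.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


def _conjunctions(schema: dict, max_order: int):
    names = sorted(schema)
    for k in range(1, min(max_order, len(names)) + 1):
        for factors in itertools.combinations(names, k):
            for levels in itertools.product(*(schema[f] for f in factors)):
                yield tuple(zip(factors, levels))


def _qualifies(literals, rows, n_positive, threshold, floor) -> bool:
    matched = [row for row in rows if all(row[f] == v for f, v in literals)]
    if not matched:
        return False
    pos = sum(row["outcome"] for row in matched)
    if Fraction(pos, len(matched)) < Fraction(threshold):
        return False
    return Fraction(pos, n_positive) >= Fraction(floor)


def brute_force_msc(table, threshold, floor, max_order) -> set[frozenset]:
    """All MSCs of a condition table, as frozensets of (factor, level)."""
    rows = table.frame.to_dict("records")
    n_positive = sum(row["outcome"] for row in rows)
    if n_positive == 0:
        return set()
    qualifying = {
        frozenset(conj)
        for conj in _conjunctions(table.schema, max_order)
        if _qualifies(conj, rows, n_positive, threshold, floor)
    }
    return {
        conj
        for conj in qualifying
        if not any(
            frozenset(sub) in qualifying
            for k in range(1, len(conj))
            for sub in itertools.combinations(conj, k)
        )
    }
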