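import pandas as pd
import pytest

from mailedfit.analyses import (
    change_condition_table,
    year1_condition_table,
    year2_condition_table,
)
from mailedfit.calibration import ConditionTable
from mailedfit.records import packaged_records
from mailedfit.synthetic import PlantedStructure, generate_table


@pytest.fixture(scope="session")
def records():
    return packaged_records()


@pytest.fixture(scope="session")
def year1_table(records):
    table, info = year1_condition_table(records)
    return table, info


@pytest.fixture(scope="session")
def year2_table(records):
    table, info = year2_condition_table(records)
    return table, info


@pytest.fixture(scope="session")
def change_table(records):
    table, info = change_condition_table(records)
    return table, info


@pytest.fixture(scope="session")
def planted_factorial():
    """Noise-free 16-case full factorial over A-D with Y = (A & B) | C."""
    spec = PlantedStructure(
        factor_names=("A", "B", "C", "D"),
        dnf=({"A": 1, "B": 1}, {"C": 1}),
        exhaustive=True,
    )
    return generate_table(spec)


def make_table(rows, schema=None, ids=None) -> ConditionTable:
    """Tiny condition table from a list of dicts (must include 'outcome')."""
    frame = pd.DataFrame(rows)
    if ids is not None:
        frame.index = ids
    if schema is None:
        schema = {c: (0, 1) for c in frame.columns if c != "outcome"}
    return ConditionTable(frame=frame, schema=schema)
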