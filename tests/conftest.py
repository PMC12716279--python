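"""Shared fixtures: toy panels, the default synthetic model, small cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hearspan import (
    StatePanel,
    Stratum,
    apply_inclusion_rule,
    build_default_spec,
    simulate_panel,
)
from hearspan.synthetic import with_overrides

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


TOY_CSV = """person_id,year,age,sex,education,state
a,2010,60,male,secondary,H
a,2011,61,male,secondary,H
a,2012,62,male,secondary,L
b,2010,70,female,tertiary,H
b,2011,71,female,tertiary,H
b,2012,72,female,tertiary,D
b,2013,73,female,tertiary,X
"""


@pytest.fixture()
def toy_csv_path(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV, encoding="utf-8")
    return path


def panel_from_rows(rows):
    """Build a StatePanel from (pid, year, age, sex, edu, state) tuples."""
    df = pd.DataFrame(
        rows, columns=["person_id", "year", "age", "sex", "education", "state"]
    )
    return StatePanel.from_frame(df, validate=False)


@pytest.fixture(scope="session")
def default_spec():
    return build_default_spec()


@pytest.fixture(scope="session")
def small_panel(default_spec):
    """A 20k-person synthetic panel, inclusion-filtered (shared, read-only)."""
    spec = with_overrides(default_spec, n_individuals=20_000, seed=424242)
    return apply_inclusion_rule(simulate_panel(spec))


@pytest.fixture(scope="session")
def male_stratum():
    return Stratum("male", "all")


@pytest.fixture()
def rng():
    return np.random.default_rng(20190931 % 2**31)
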