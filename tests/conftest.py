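"""Shared fixtures: the study-scale design and simulated datasets.

Expensive artifacts (design search, study-scale simulations, the mixed
logit fit) are session-scoped so every test module reuses them.
"""

import numpy as np
import pytest

import ruraldce as r
from ruraldce.data import Attribute, AttributeSchema


@pytest.fixture(scope="session")
def schema():
    return r.default_schema()


@pytest.fixture(scope="session")
def toy_schema():
    """Two binary attributes — small enough for exhaustive checks."""
    return AttributeSchema(
        (
            Attribute("first", ("lo", "hi"), reference="lo"),
            Attribute("second", ("off", "on"), reference="off"),
        )
    )


@pytest.fixture(scope="session")
def paper_design(schema):
    """24 paired tasks, 3 blocks of 8 — the study layout."""
    design, diag = r.build_paired_design(
        schema, n_tasks=24, n_blocks=3, seed=1, n_iter=1500
    )
    return design, diag


@pytest.fixture(scope="session")
def clogit_dataset(schema, paper_design):
    """352 respondents simulated under homogeneous preferences."""
    design, _ = paper_design
    dataset, betas, _ = r.simulate_study(
        r.reference_clogit_dgp(), design, schema, n_respondents=352, seed=7
    )
    return dataset


@pytest.fixture(scope="session")
def mixl_dataset(schema, paper_design):
    """352 respondents under the reference mixed-logit preferences."""
    design, _ = paper_design
    dataset, betas, _ = r.simulate_study(
        r.reference_mixl_dgp(), design, schema, n_respondents=352, seed=7
    )
    return dataset


@pytest.fixture(scope="session")
def mixl_fit(schema, mixl_dataset):
    """Study-scale mixed logit fit at a reduced number of Halton draws."""
    return r.fit_mixl(mixl_dataset, schema, R=200, seed=3)


@pytest.fixture(scope="session")
def lcm_dataset(schema, paper_design):
    """2,000 respondents under the three-class preference structure."""
    design, _ = paper_design
    dataset, _, classes = r.simulate_study(
        r.reference_lcm_dgp(), design, schema, n_respondents=2000, seed=7
    )
    return dataset, classes


@pytest.fixture(scope="session")
def lcm_selection(schema, lcm_dataset):
    """AIC class-count selection over C in {1, 2, 3, 4}."""
    dataset, _ = lcm_dataset
    return r.select_classes(dataset, schema, C_range=(1, 2, 3, 4), seed=11, n_starts=2)
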