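"""Shared fixtures: toy hand-checkable objects and the reference synthetic run.

The heavier synthetic-pipeline objects are session-scoped so the whole
suite performs the reference simulation and scoring exactly once.
"""

import numpy as np
import pandas as pd
import pytest

import stemscore as ss


@pytest.fixture
def toy_matrix() -> ss.ExpressionMatrix:
    """4 genes × 1 sample with expression 4 > 3 > 2 > 1 (A > B > C > D)."""
    return ss.ExpressionMatrix(
        pd.DataFrame({"s1": [4.0, 3.0, 2.0, 1.0]}, index=["A", "B", "C", "D"])
    )


@pytest.fixture
def toy_ranks(toy_matrix) -> pd.Series:
    return ss.rank_transform(toy_matrix)["s1"]


@pytest.fixture(scope="session")
def design() -> ss.SimulationDesign:
    """The frozen reference design (seed 1)."""
    return ss.SimulationDesign(seed=1)


@pytest.fixture(scope="session")
def stem_data(design):
    return ss.gen_stem_somatic(design)


@pytest.fixture(scope="session")
def panel_data(design):
    return ss.gen_cellline_panel(design)


@pytest.fixture(scope="session")
def cohort_data(design):
    return ss.gen_tumor_cohort(design)


@pytest.fixture(scope="session")
def stem_scores(stem_data):
    return ss.score_collection(stem_data.expression, stem_data.collection)


@pytest.fixture(scope="session")
def panel_scores(panel_data):
    return ss.score_collection(panel_data.expression, panel_data.collection)


@pytest.fixture(scope="session")
def distilled(stem_scores, stem_data, panel_scores):
    return ss.distill(
        stem_scores, stem_data.labels, panel_scores, stem_data.collection
    )


@pytest.fixture(scope="session")
def cohort_scores(cohort_data, distilled):
    _, signature = distilled
    return ss.score_samples(cohort_data.expression, signature)
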