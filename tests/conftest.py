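"""Shared fixtures: synthetic studies at several sizes and one full grouping run.

Expensive artefacts (the default-size study and its bootstrap grouping run)
are session-scoped so the recovery, analogue and acceptance tests share
them instead of recomputing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from grouprax.design import StudyDesign
from grouprax.matrix import FeatureMatrix
from grouprax.pipeline import omics_grouping
from grouprax.simulate import AZO_EXCLUSIONS, SimConfig, simulate_study

SMALL_FEATURES = {"polar": 60, "apolar": 50, "transcriptomics": 200}


@pytest.fixture(scope="session")
def azo_design() -> StudyDesign:
    return StudyDesign(
        substances=["DY3", "S1", "SRG", "DO25", "DR1", "DR13", "DO61"],
        dose_levels=["low", "medium", "high"],
        time_points=["2h", "24h", "48h"],
    )


@pytest.fixture(scope="session")
def small_study():
    """Reduced-feature study for fast unit tests."""
    return simulate_study(SimConfig(seed=11, n_features=dict(SMALL_FEATURES)))


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions (complete factorial, seed 0)."""
    return simulate_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def missing_groups_study():
    """Default study with the historical missing-treatment-group pattern."""
    return simulate_study(
        SimConfig(seed=0, n_features=dict(SMALL_FEATURES), exclusions=list(AZO_EXCLUSIONS))
    )


@pytest.fixture(scope="session")
def default_run(default_study):
    """Full multi-omics grouping of the default study (archive retained)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return omics_grouping(
            default_study.layers,
            default_study.design,
            n_boot=1000,
            seed=0,
            keep_archive=True,
        )


def toy_matrix(values: np.ndarray, layer: str = "polar") -> FeatureMatrix:
    """Small FeatureMatrix with one treated group and controls."""
    n = values.shape[0]
    half = n // 2
    meta = pd.DataFrame(
        {
            "substance": ["X"] * n,
            "dose_level": ["high"] * half + ["control"] * (n - half),
            "time_point": ["24h"] * n,
            "replicate": list(range(1, half + 1)) + list(range(1, n - half + 1)),
            "batch": ["b1"] * n,
        },
        index=[f"s{i}" for i in range(n)],
    )
    vals = pd.DataFrame(
        values, index=meta.index, columns=[f"f{j}" for j in range(values.shape[1])]
    )
    return FeatureMatrix(layer, vals, meta)
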