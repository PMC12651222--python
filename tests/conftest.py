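"""Shared fixtures.

The repeated-CV runs are expensive, so the cohort-level experiments used by
several acceptance tests (null calibration, signal recovery, biomarker
recovery) are computed once per session and shared. The graph-model width is
reduced relative to the library defaults for these runs; cohort sizes, effect
sizes and class imbalance are the study conditions themselves and are not
reduced.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from omicstack import (
    CVPlan, HybridStackModel, PipelineConfig, SimulationConfig, generate_cohort,
)
from omicstack.gat import GATConfig

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)

#: scaled-down graph model used inside cross-validated runs
CV_GAT = dict(heads=2, hidden=4, epochs=60, patience=10, dtype="float32")


def cv_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(gat=GATConfig(seed=seed, **CV_GAT), inner_folds=3,
                          seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    """Small but complete cohort for plumbing tests."""
    return generate_cohort(SimulationConfig(
        n_per_class=(20, 20, 10), n_genes=60, n_mirnas=12, n_cpgs=30,
        n_informative_genes=8, seed=5,
    ))


@pytest.fixture(scope="session")
def null_run():
    """Effect-0 cohort (n=140, 3 classes), repeated 5-fold x 3."""
    cohort = generate_cohort(SimulationConfig(effect_size=0.0, seed=1))
    model = HybridStackModel.from_cohort(cohort, cv_config(seed=1))
    results = model.fit(CVPlan(n_folds=5, n_repeats=3, seed=1))
    return cohort, results


@pytest.fixture(scope="session")
def signal_runs():
    """Effect-2.0 cohorts, n=(60,60,20), 200 genes, 20 planted; 3 seeds."""
    out = {}
    for seed in (11, 12, 13):
        cohort = generate_cohort(SimulationConfig(seed=seed))
        model = HybridStackModel.from_cohort(cohort, cv_config(seed=seed))
        out[seed] = (cohort, model.fit(CVPlan(n_folds=5, n_repeats=1, seed=seed)))
    return out
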