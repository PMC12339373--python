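"""Shared fixtures: synthetic cohorts and one fitted cross-validation run.

The expensive artifacts (a fast-mode cohort and a 10-fold CV run with
kept fold models) are session-scoped so model, interpretability and
evaluation tests share them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from neurofuse.evaluate import EvalConfig, cross_validate
from neurofuse.model import FusionDataset, fast_model_config
from neurofuse.synth import fast_config, gen_connectivity_cohort

warnings.filterwarnings("ignore", message="expected 10 fold models")


@pytest.fixture(scope="session")
def fast_cohort():
    """Fast-mode connectivity cohort: 20 ROIs, 120 subjects, planted signature."""
    return gen_connectivity_cohort(fast_config(seed=0))


@pytest.fixture(scope="session")
def fast_dataset(fast_cohort):
    return FusionDataset.from_cohort(fast_cohort)


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-subject cohort for cheap harness tests."""
    cohort = gen_connectivity_cohort(fast_config(seed=7, n_subjects=40))
    return FusionDataset.from_cohort(cohort)


@pytest.fixture(scope="session")
def e2e_runs(fast_dataset):
    """Three augmented 10-fold CV runs of the fusion model, fold models kept.

    Importance read-outs average over the fold models of several
    predictive runs; tests of prediction, importance and recovery share
    these runs.
    """
    cfg = EvalConfig(model=fast_model_config(20))
    return cross_validate(fast_dataset, cfg, [0, 1, 2], keep_models=True)


@pytest.fixture(scope="session")
def cv_run(e2e_runs):
    """One augmented 10-fold CV run of the fusion model, fold models kept."""
    return e2e_runs[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
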