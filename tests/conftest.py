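import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swarmstack import dataio, synthgen
from swarmstack.dataio import ClinicalDataset, SplitSpec
from swarmstack.fitness import FitnessEvaluator

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dataset(X, y, names=None) -> ClinicalDataset:
    X = np.asarray(X, dtype=float)
    return ClinicalDataset(
        feature_names=names or [f"f{j}" for j in range(X.shape[1])],
        X=X,
        y=np.asarray(y, dtype=int),
        missing_mask=np.zeros(X.shape, dtype=bool),
    )


@pytest.fixture(scope="session")
def benchmark_train():
    """The fixed synthetic benchmark, fully preprocessed, training part."""
    ds = synthgen.generate(synthgen.BENCHMARK)
    ds = dataio.impute_mean(ds)
    ds = dataio.smote(ds, seed=1)
    ds, _ = dataio.minmax_normalize(ds)
    train, _ = dataio.stratified_split(ds, SplitSpec(0.6, True, 3))
    return train


@pytest.fixture(scope="session")
def benchmark_evaluator(benchmark_train):
    """One cached fitness evaluator shared by every benchmark-scale test."""
    return FitnessEvaluator(benchmark_train, folds=5, seed=11)


@pytest.fixture(scope="session")
def small_train():
    """A cheap 5-feature separable dataset for selector unit tests."""
    spec = dataclasses.replace(synthgen.BENCHMARK, n=80, m_informative=2,
                               m_noise=3, missing_rate=0.0, seed=7)
    ds = synthgen.generate(spec)
    ds = dataio.smote(ds, seed=2)
    ds, _ = dataio.minmax_normalize(ds)
    return ds


@pytest.fixture()
def small_evaluator(small_train):
    return FitnessEvaluator(small_train, folds=3, seed=5)
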