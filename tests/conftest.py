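"""Shared fixtures: baseline surrogates and dt-matched evaluators.

Population-scale tests run the simulator at dt = 0.1 ms (the coarsest
resolution the solver accepts); accuracy-sensitive tests build their own
finer-dt traces.  Targets are always generated at the same dt as the
evaluator that consumes them.
"""

import numpy as np
import pytest

from condpop.fitness import ModelEvaluator
from condpop.fixtures import generate_feature_targets, make_baseline_models
from condpop.model import SolverOptions

FAST_DT = 0.1


@pytest.fixture(scope="session")
def baselines():
    return make_baseline_models()


@pytest.fixture(scope="session")
def fast_solver():
    return SolverOptions(dt=FAST_DT)


@pytest.fixture(scope="session")
def fast_targets(baselines, fast_solver):
    return {
        name: generate_feature_targets(cfg, solver=fast_solver)
        for name, cfg in baselines.items()
    }


@pytest.fixture(scope="session")
def fast_evaluators(baselines, fast_targets, fast_solver):
    return {
        name: ModelEvaluator(baseline=cfg, targets=fast_targets[name], solver=fast_solver)
        for name, cfg in baselines.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
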