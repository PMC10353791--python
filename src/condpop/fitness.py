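"""Model evaluation pipeline: conductance vector → Pareto efficiency P.

Bundles the simulator, feature extraction and fitness scoring behind one
callable, the objective used by the search and by every population protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from condpop.engine import SimulationError, run_protocols
from condpop.features import (
    FeatureTargets,
    FitnessResult,
    NONSPIKING_SENTINEL,
    extract_features,
    feature_fitness,
)
from condpop.model import NeuronConfig, SolverOptions

STANDARD_AMPLITUDES = (50.0, 90.0)


@dataclass
class ModelEvaluator:
    """Evaluate conductance vectors of a fixed model structure.

    ``evaluate_config`` runs the standard 50/90 pA protocols (one shared
    settle-in) and scores the features against ``targets``.  A simulation
    blow-up counts as a maximally unfit model (sentinel P), never an
    exception: random population sampling must be able to traverse
    pathological corners of conductance space.
    """

    baseline: NeuronConfig
    targets: FeatureTargets
    solver: SolverOptions = field(default_factory=SolverOptions)
    n_evaluations: int = 0

    def evaluate_config(self, config: NeuronConfig) -> FitnessResult:
        self.n_evaluations += 1
        try:
            traces = run_protocols(config, STANDARD_AMPLITUDES, solver=self.solver)
        except SimulationError:
            return FitnessResult(
                per_feature={},
                pareto_efficiency=NONSPIKING_SENTINEL,
                valid=False,
                sentinel_applied=True,
            )
        feats = extract_features(traces[50.0], traces[90.0])
        return feature_fitness(feats, self.targets)

    def evaluate_array(self, free_values: np.ndarray) -> float:
        """P for a free-parameter array laid out as ``baseline.free_keys``."""
        config = self.baseline.with_free_array(np.asarray(free_values, dtype=float))
        return self.evaluate_config(config).pareto_efficiency

    def __call__(self, free_values: np.ndarray) -> float:
        return self.evaluate_array(free_values)


__all__ = ["ModelEvaluator", "STANDARD_AMPLITUDES"]
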