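"""Derivative-free conjugate-direction search for valid conductance vectors.

Powell-style successive line minimisations: each sweep line-minimises along a
maintained direction set (initially the coordinate axes), then replaces the
direction of largest gain with the sweep's aggregate displacement.  Slopes
are estimated from two sample points at ±5% of the corresponding parameter
values.  On flat regions (zero gradient, typically non-spiking models) the
probe step escalates in +5-percentage-point increments up to ±50%; if the
landscape is still flat or the local minimum is not valid, the parameters
are randomised in an iteratively increasing range (±10% → ±50% in ±10%
steps).  The search terminates as soon as P drops below the validity
threshold, when stalled, or at the iteration cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from condpop.features import VALIDITY_THRESHOLD
from condpop.model import NeuronConfig


class Objective:
    """Wrap a P-valued callable with an evaluation counter."""

    def __init__(self, fn):
        self._fn = fn
        self.n_evaluations = 0

    def __call__(self, x: np.ndarray) -> float:
        self.n_evaluations += 1
        p = float(self._fn(np.asarray(x, dtype=float)))
        if not math.isfinite(p):
            raise ValueError("objective returned a non-finite value")
        return p


@dataclass
class SearchConfig:
    probe_step: float = 0.05
    max_probe_step: float = 0.50
    probe_step_increment: float = 0.05
    randomization_start: float = 0.10
    randomization_step: float = 0.10
    randomization_max: float = 0.50
    success_threshold: float = VALIDITY_THRESHOLD
    max_outer_iterations: int = 50
    max_line_evaluations: int = 20
    min_improvement: float = 1e-6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.probe_step <= self.max_probe_step <= 1.0):
            raise ValueError("need 0 < probe_step <= max_probe_step <= 1")
        if self.success_threshold <= 0.0:
            raise ValueError("success threshold must be positive")


@dataclass
class SearchResult:
    best_x: np.ndarray
    best_P: float
    trajectory: list[float]
    iterations: int
    termination: str  # threshold_met | max_iterations | stalled
    event_log: list[dict] = field(default_factory=list)
    n_evaluations: int = 0

    @property
    def succeeded(self) -> bool:
        return self.termination == "threshold_met"


@dataclass
class ProbeResult:
    slope: float
    flat: bool
    f_plus: float
    f_minus: float


def probe_direction(
    objective, point: np.ndarray, dimension: int, step_fraction: float
) -> ProbeResult:
    """Central-difference slope along one coordinate at ±step_fraction.

    The two sample points are at ``(1 ± step)`` times the coordinate value;
    a dimension is flagged flat when both evaluations agree exactly (zero
    gradient plateau).
    """
    point = np.asarray(point, dtype=float)
    x = point[dimension]
    hi = point.copy()
    lo = point.copy()
    hi[dimension] = x * (1.0 + step_fraction)
    lo[dimension] = x * (1.0 - step_fraction)
    f_plus = objective(hi)
    f_minus = objective(lo)
    h = hi[dimension] - lo[dimension]
    slope = (f_plus - f_minus) / h if h != 0.0 else 0.0
    return ProbeResult(slope=slope, flat=f_plus == f_minus, f_plus=f_plus, f_minus=f_minus)


def _relative_scale(point: np.ndarray, direction: np.ndarray, fraction: float) -> float:
    """Step size t so that max relative coordinate change equals ``fraction``."""
    ref = np.where(point > 0.0, point, np.max(point) if np.max(point) > 0 else 1.0)
    rel = np.abs(direction) / ref
    m = rel.max()
    return fraction / m if m > 0.0 else 0.0


def line_minimize(
    objective,
    point: np.ndarray,
    direction: np.ndarray,
    config: SearchConfig,
    f0: float | None = None,
    step_fraction: float | None = None,
):
    """Minimise along ``±direction`` by two probes plus expanding steps.

    Two sample points at ±``step_fraction`` (relative scale) pick the descent
    side; steps then expand geometrically while the objective keeps falling,
    with a total budget of ``max_line_evaluations``.  The returned point is
    never worse than the input.  Coordinates are clipped at zero (densities).
    """
    point = np.asarray(point, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if not np.any(direction):
        raise ValueError("line direction must be nonzero")
    frac = step_fraction if step_fraction is not None else config.probe_step
    t0 = _relative_scale(point, direction, frac)
    if t0 == 0.0:
        f = objective(point) if f0 is None else f0
        return point, f, 0
    evals = 0
    if f0 is None:
        f0 = objective(point)
        evals += 1
    fp = objective(np.clip(point + t0 * direction, 0.0, None))
    fm = objective(np.clip(point - t0 * direction, 0.0, None))
    evals += 2
    best_x, best_f = point, f0
    if fp < best_f:
        best_x, best_f = np.clip(point + t0 * direction, 0.0, None), fp
    if fm < best_f:
        best_x, best_f = np.clip(point - t0 * direction, 0.0, None), fm
    golden = 1.618033988749895
    if fp == f0 and fm == f0:
        # flat plateau (typical of the non-spiking sentinel): nothing to refine
        return best_x, best_f, evals
    if min(fp, fm) >= f0:
        # both probes uphill: the minimum (if any) lies between them —
        # refine by golden section on [-t0, t0] with the remaining budget
        invphi = 1.0 / golden
        a, b = -t0, t0
        fa, fb = fm, fp

        def at0(t):
            return np.clip(point + t * direction, 0.0, None)

        c = b - (b - a) * invphi
        d = a + (b - a) * invphi
        fc = fd = None
        while evals < config.max_line_evaluations:
            if fc is None:
                fc = objective(at0(c))
                evals += 1
                if fc < best_f:
                    best_x, best_f = at0(c), fc
                continue
            if fd is None:
                fd = objective(at0(d))
                evals += 1
                if fd < best_f:
                    best_x, best_f = at0(d), fd
                continue
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - (b - a) * invphi
                fc = None
            else:
                a, c, fc = c, d, fd
                d = a + (b - a) * invphi
                fd = None
        return best_x, best_f, evals
    sign = 1.0 if fp <= fm else -1.0

    def at(t):
        return np.clip(point + sign * t * direction, 0.0, None)

    # expansion: geometric steps along the descent side until the value rises
    ts = [0.0, t0]
    fs = [f0, fp if sign > 0 else fm]
    t = t0
    while evals < config.max_line_evaluations:
        t *= golden
        f = objective(at(t))
        evals += 1
        ts.append(t)
        fs.append(f)
        if f < best_f:
            best_x, best_f = at(t), f
        if f > fs[-2]:
            break
    # golden-section refinement inside the bracket around the best sample
    i = int(np.argmin(fs))
    lo = ts[i - 1] if i > 0 else 0.0
    hi = ts[i + 1] if i + 1 < len(ts) else ts[i]
    if hi > lo:
        invphi = 1.0 / golden
        a, b = lo, hi
        c = b - (b - a) * invphi
        d = a + (b - a) * invphi
        fc = fd = None
        while evals < config.max_line_evaluations:
            if fc is None:
                fc = objective(at(c))
                evals += 1
                if fc < best_f:
                    best_x, best_f = at(c), fc
                continue
            if fd is None:
                fd = objective(at(d))
                evals += 1
                if fd < best_f:
                    best_x, best_f = at(d), fd
                continue
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - (b - a) * invphi
                fc = None
            else:
                a, c, fc = c, d, fd
                d = a + (b - a) * invphi
                fd = None
    return best_x, best_f, evals


def conjugate_direction_search(
    objective,
    start: np.ndarray,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Powell-style sweeps with step escalation and randomised restarts."""
    config = config or SearchConfig()
    obj = objective if isinstance(objective, Objective) else Objective(objective)
    rng = np.random.default_rng(config.rng_seed)
    x = np.asarray(start, dtype=float).copy()
    if np.any(x < 0.0):
        raise ValueError("start point must be non-negative")
    n = len(x)
    directions = [np.eye(n)[i] for i in range(n)]
    log: list[dict] = []
    trajectory: list[float] = []

    f = obj(x)
    best_x, best_f = x.copy(), f
    trajectory.append(f)
    if f < config.success_threshold:
        return SearchResult(best_x, best_f, trajectory, 0, "threshold_met", log, obj.n_evaluations)

    step = config.probe_step
    rand_range = config.randomization_start
    rand_rounds_exhausted = 0
    termination = "max_iterations"
    it = 0
    for it in range(1, config.max_outer_iterations + 1):
        x_sweep0 = x.copy()
        f_sweep0 = f
        gains = np.zeros(len(directions))
        for di, d in enumerate(directions):
            x_new, f_new, _ = line_minimize(obj, x, d, config, f0=f, step_fraction=step)
            log.append({"iteration": it, "P": f_new, "action": "line"})
            gains[di] = f - f_new
            x, f = x_new, f_new
            if f < best_f:
                best_x, best_f = x.copy(), f
            if f < config.success_threshold:
                trajectory.append(f)
                return SearchResult(
                    best_x, best_f, trajectory, it, "threshold_met", log, obj.n_evaluations
                )
        disp = x - x_sweep0
        if np.any(disp):
            # replace the direction of largest gain with the aggregate displacement
            di = int(np.argmax(gains))
            directions[di] = disp / np.linalg.norm(disp)
            x_new, f_new, _ = line_minimize(obj, x, directions[di], config, f0=f, step_fraction=step)
            log.append({"iteration": it, "P": f_new, "action": "line"})
            x, f = x_new, f_new
            if f < best_f:
                best_x, best_f = x.copy(), f
        trajectory.append(f)
        if f < config.success_threshold:
            return SearchResult(
                best_x, best_f, trajectory, it, "threshold_met", log, obj.n_evaluations
            )

        improved = f_sweep0 - f > config.min_improvement
        if improved:
            step = config.probe_step  # de-escalate once progress resumes
            continue
        if step + config.probe_step_increment <= config.max_probe_step + 1e-12:
            step = step + config.probe_step_increment
            log.append({"iteration": it, "P": f, "action": "escalate", "step": round(step, 4)})
            continue
        # escalation exhausted: randomised restart in an increasing range
        factors = rng.uniform(1.0 - rand_range, 1.0 + rand_range, size=n)
        x = np.clip(best_x * factors, 0.0, None)
        f = obj(x)
        log.append({"iteration": it, "P": f, "action": "randomize", "range": round(rand_range, 4)})
        if f < best_f:
            best_x, best_f = x.copy(), f
        if rand_range + config.randomization_step <= config.randomization_max + 1e-12:
            rand_range += config.randomization_step
        else:
            # full schedule spent: reset directions and step, count the round
            rand_rounds_exhausted += 1
            rand_range = config.randomization_start
            directions = [np.eye(n)[i] for i in range(n)]
            step = config.probe_step
            if rand_rounds_exhausted >= 2:
                termination = "stalled"
                break

    return SearchResult(best_x, best_f, trajectory, it, termination, log, obj.n_evaluations)


def knockout_refit(
    config: NeuronConfig,
    channel_name: str,
    targets,
    search_config: SearchConfig | None = None,
    solver=None,
):
    """Zero a channel everywhere and re-optimise the remaining parameters.

    The knocked-out channel's densities are fixed at 0 and excluded from the
    search dimensions; the remaining non-frozen parameters start from the
    baseline values.  Returns ``(SearchResult, refitted NeuronConfig)``.
    """
    from dataclasses import replace as _replace

    from condpop.fitness import ModelEvaluator
    from condpop.model import SolverOptions

    if channel_name in config.frozen_channels:
        raise ValueError(f"cannot knock out frozen passive channel {channel_name!r}")
    if channel_name not in {c.name for c in config.channels}:
        raise ValueError(f"channel {channel_name!r} not present in the model")
    table = dict(config.conductance_table)
    for key in table:
        if key[0] == channel_name:
            table[key] = 0.0
    ko = _replace(
        config,
        conductance_table=table,
        frozen_channels=config.frozen_channels | {channel_name},
    )
    evaluator = ModelEvaluator(
        baseline=ko, targets=targets, solver=solver or SolverOptions()
    )
    result = conjugate_direction_search(
        Objective(evaluator.evaluate_array), ko.free_array(), search_config
    )
    return result, ko.with_free_array(result.best_x)


__all__ = [
    "Objective",
    "SearchConfig",
    "SearchResult",
    "ProbeResult",
    "probe_direction",
    "line_minimize",
    "conjugate_direction_search",
    "knockout_refit",
]
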