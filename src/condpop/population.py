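"""Population-level protocols over conductance space.

All operations work on *free-parameter* vectors (the sampled, non-frozen
subset of a model's conductance table) and an evaluator mapping one vector
to its Pareto efficiency P.  Any callable with that contract works — the
full simulator pipeline (:class:`condpop.fitness.ModelEvaluator`) or an
analytic rule such as the toy-model validity criterion — which is how the
statistical machinery is validated against closed-form oracles.

Protocols: uniform 0–2× population sampling with validity classification,
range sweeps around a valid reference, pairwise conductance correlations,
random-walk stability, isoform-diversity expansion, and hyperplane
connectivity between valid solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from condpop.features import VALIDITY_THRESHOLD
from condpop.model import NeuronConfig, add_isoform


def wilson_ci(n_valid: int, n_total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial fraction."""
    lo, hi = proportion_confint(n_valid, n_total, alpha=alpha, method="wilson")
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# sampling and classification
# --------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    baseline: NeuronConfig
    n_samples: int = 20_000
    fold_range: tuple[float, float] = (0.0, 2.0)
    rng_seed: int = 0
    #: permit zero baseline densities (they sample as constant zero); used for
    #: refitted models where the search legitimately silences a channel copy
    allow_zero: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.fold_range
        if lo < 0.0 or hi <= lo:
            raise ValueError("fold_range must satisfy 0 <= lo < hi")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class PopulationResult:
    samples: np.ndarray  # (n, d) free-parameter matrix, mS/cm²
    P: np.ndarray  # per-sample Pareto efficiency
    valid: np.ndarray  # bool flags (P < threshold)
    fraction: float
    ci: tuple[float, float]
    keys: list | None = None

    @property
    def valid_rows(self) -> np.ndarray:
        return self.samples[self.valid]


def sample_population(config: PopulationConfig) -> np.ndarray:
    """Uniform fold-range sampling of the free conductance densities.

    Each non-frozen density is drawn independently and uniformly from
    [lo, hi] times its baseline value; frozen densities never enter the
    matrix (they stay at baseline inside the evaluator).
    """
    base = config.baseline.free_array()
    if np.any(base == 0.0) and not config.allow_zero:
        keys = [k for k, b in zip(config.baseline.free_keys, base) if b == 0.0]
        raise ValueError(f"baseline density is zero for sampled keys {keys}; range degenerate")
    lo, hi = config.fold_range
    rng = np.random.default_rng(config.rng_seed)
    factors = rng.uniform(lo, hi, size=(config.n_samples, len(base)))
    return factors * base


def evaluate_rows(samples: np.ndarray, evaluator, vectorized: bool = False) -> np.ndarray:
    if vectorized:
        return np.asarray(evaluator(samples), dtype=float)
    return np.array([float(evaluator(row)) for row in samples], dtype=float)


def classify_population(
    samples: np.ndarray,
    evaluator,
    threshold: float = VALIDITY_THRESHOLD,
    vectorized: bool = False,
    keys=None,
) -> PopulationResult:
    """Per-row P, validity flags and the valid fraction with a Wilson 95% CI."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        raise ValueError("empty sample matrix")
    P = evaluate_rows(samples, evaluator, vectorized=vectorized)
    valid = P < threshold
    frac = float(valid.mean())
    return PopulationResult(
        samples=samples,
        P=P,
        valid=valid,
        fraction=frac,
        ci=wilson_ci(int(valid.sum()), len(valid)),
        keys=keys,
    )


def range_sweep(
    baseline: np.ndarray,
    half_widths,
    evaluator,
    n_per: int = 5_000,
    seed: int = 0,
    threshold: float = VALIDITY_THRESHOLD,
    vectorized: bool = False,
) -> pd.DataFrame:
    """Valid fraction in shrinking neighbourhoods of a valid reference.

    For each half-width w, ``n_per`` vectors are sampled uniformly in
    [1−w, 1+w] times the reference and classified; returns a tidy frame of
    fractions with Wilson CIs.
    """
    baseline = np.asarray(baseline, dtype=float)
    rows = []
    for i, w in enumerate(half_widths):
        if w < 0.0 or w > 1.0:
            raise ValueError(f"half-width {w} outside [0, 1]")
        if w == 0.0:
            samples = np.tile(baseline, (n_per, 1))
        else:
            rng = np.random.default_rng(seed + i)
            factors = rng.uniform(1.0 - w, 1.0 + w, size=(n_per, len(baseline)))
            samples = factors * baseline
        res = classify_population(samples, evaluator, threshold, vectorized=vectorized)
        rows.append(
            {"half_width": w, "fraction": res.fraction, "ci_lo": res.ci[0], "ci_hi": res.ci[1]}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------

def pairwise_correlations(
    valid_rows: np.ndarray, names=None, alpha: float = 0.01
) -> dict[str, pd.DataFrame]:
    """Pearson r, two-sided p-values and significance flags for all pairs.

    Constant columns yield NaN correlations and are never flagged.  p-values
    use the exact t transform t = r·sqrt((n−2)/(1−r²)); no multiple-testing
    correction is applied (flags are reported at p < 0.01).
    """
    X = np.atleast_2d(np.asarray(valid_rows, dtype=float))
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 valid rows for correlations")
    if names is None:
        names = [f"p{i}" for i in range(d)]
    sd = X.std(axis=0)
    r = np.full((d, d), np.nan)
    ok = sd > 0.0
    if ok.sum() >= 2:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        idx = np.flatnonzero(ok)
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                r[ia, ib] = sub[a, b]
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = np.clip(r, -0.9999999999, 0.9999999999)
        t = rc * np.sqrt((n - 2) / (1.0 - rc**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    flags = (p < alpha) & ~np.isnan(r)
    np.fill_diagonal(flags, False)
    return {
        "r": pd.DataFrame(r, index=names, columns=names),
        "p": pd.DataFrame(p, index=names, columns=names),
        "significant": pd.DataFrame(flags, index=names, columns=names),
    }


def mean_offdiagonal_r(corr: pd.DataFrame) -> float:
    r = corr.to_numpy()
    iu = np.triu_indices_from(r, k=1)
    vals = r[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else math.nan


# --------------------------------------------------------------------------
# random walks
# --------------------------------------------------------------------------

@dataclass
class WalkResult:
    steps: np.ndarray  # steps survived per repetition
    bin_width: int = 4

    @property
    def mean_steps(self) -> float:
        return float(self.steps.mean())

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """Counts and bin edges; edges are multiples of the 4-step bin width."""
        top = (int(self.steps.max()) // self.bin_width + 1) * self.bin_width
        edges = np.arange(0, top + self.bin_width, self.bin_width)
        counts, edges = np.histogram(self.steps, bins=edges)
        return counts, edges


def random_walk(
    start_vector: np.ndarray,
    evaluator,
    step_fraction: float = 0.05,
    max_steps: int = 1_000,
    seed: int = 0,
    threshold: float = VALIDITY_THRESHOLD,
) -> int:
    """Multiplicative random walk until validity is lost.

    Each step multiplies every walked parameter by an independent uniform
    factor in [1−step_fraction, 1+step_fraction] (changing all parameters
    counts as one step); the walk halts at the first invalid state and
    returns the number of completed valid steps.
    """
    x = np.asarray(start_vector, dtype=float).copy()
    if not float(evaluator(x)) < threshold:
        raise ValueError("random walk must start from a valid parameter vector")
    rng = np.random.default_rng(seed)
    for step in range(max_steps):
        x = x * rng.uniform(1.0 - step_fraction, 1.0 + step_fraction, size=len(x))
        if not float(evaluator(x)) < threshold:
            return step
    return max_steps


def walk_ensemble(
    start_vectors: np.ndarray,
    evaluator,
    reps: int = 2_000,
    step_fraction: float = 0.05,
    max_steps: int = 1_000,
    seed: int = 0,
    threshold: float = VALIDITY_THRESHOLD,
) -> WalkResult:
    """Distribution of walk survival over ``reps`` repetitions.

    ``start_vectors`` may be a single vector or a stack of valid vectors;
    repetitions cycle through the stack.  The histogram convention uses a
    bin width of 4 steps.
    """
    starts = np.atleast_2d(np.asarray(start_vectors, dtype=float))
    steps = np.empty(reps, dtype=np.int64)
    for rep in range(reps):
        steps[rep] = random_walk(
            starts[rep % len(starts)],
            evaluator,
            step_fraction=step_fraction,
            max_steps=max_steps,
            seed=seed + rep,
            threshold=threshold,
        )
    return WalkResult(steps=steps)


# --------------------------------------------------------------------------
# isoform expansion
# --------------------------------------------------------------------------

@dataclass
class ExpansionResult:
    config: NeuronConfig  # best refined expanded model
    best_P: float
    succeeded: bool  # best refined model satisfies P < 2
    candidate_P: list[float] = field(default_factory=list)
    n_isoforms: int = 0


def expand_isoforms(
    base5: NeuronConfig,
    k: int,
    targets,
    search_config=None,
    initial_sample_size: int = 1_000,
    seed: int = 0,
    solver=None,
    parents: tuple[str, str] = ("BK", "Cav22"),
) -> ExpansionResult:
    """Grow the 5-channel model by ``k`` artificial isoforms and re-fit.

    Isoforms of the remaining K (BK) and Ca (Cav22) channels are added in
    alternation, each with gate time constants rescaled by uniform factors
    on [0, 2).  Conductances of the expanded roster are then sampled in a
    two-fold range, the three best-P candidates are refined with the
    conjugate-direction search, and the best refined model becomes the new
    baseline.
    """
    from condpop.fitness import ModelEvaluator
    from condpop.model import SolverOptions
    from condpop.search import SearchConfig, conjugate_direction_search

    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    config = base5
    copies: dict[str, list[str]] = {p: [p] for p in parents}
    for i in range(k):
        parent = parents[i % len(parents)]
        config = add_isoform(config, parent, rng, density_scale=1.0)
        copies[parent].append(config.channels[-1].name)
    # split each parent's baseline density evenly across its copies, so the
    # expanded default keeps the same per-class totals as the 5-channel model
    table = dict(config.conductance_table)
    for parent, members in copies.items():
        m = len(members)
        for (chan, region), dens in base5.conductance_table.items():
            if chan == parent:
                for member in members:
                    table[(member, region)] = dens / m
    from dataclasses import replace as _dc_replace

    config = _dc_replace(config, conductance_table=table)
    solver = solver or SolverOptions()
    evaluator = ModelEvaluator(baseline=config, targets=targets, solver=solver)
    if k == 0:
        p0 = evaluator.evaluate_array(config.free_array())
        return ExpansionResult(config, p0, p0 < VALIDITY_THRESHOLD, [p0], 0)

    base = config.free_array()
    if initial_sample_size < 3:
        raise ValueError("initial_sample_size must be >= 3")
    factors = rng.uniform(0.0, 2.0, size=(initial_sample_size, len(base)))
    samples = factors * base
    P = np.array([evaluator.evaluate_array(row) for row in samples])
    order = np.argsort(P, kind="stable")[:3]  # exactly 3 candidates enter refinement

    search_config = search_config or SearchConfig(rng_seed=seed)
    best = None
    candidate_P = []
    for rank, idx in enumerate(order):
        res = conjugate_direction_search(
            evaluator.evaluate_array, samples[idx], search_config
        )
        candidate_P.append(res.best_P)
        if best is None or res.best_P < best.best_P:
            best = res
    new_config = config.with_free_array(best.best_x)
    return ExpansionResult(
        config=new_config,
        best_P=best.best_P,
        succeeded=best.best_P < VALIDITY_THRESHOLD,
        candidate_P=candidate_P,
        n_isoforms=k,
    )


# --------------------------------------------------------------------------
# hyperplanes
# --------------------------------------------------------------------------

@dataclass
class HyperplaneResult:
    kind: str  # "pair" | "triplet"
    weights: np.ndarray  # (9,) for pairs; (n_points, 2) for triplets
    P: np.ndarray
    connected: bool | None = None
    masked: np.ndarray | None = None  # negative-parameter mask (triplets)


PAIR_WEIGHTS = np.round(np.arange(0.1, 0.95, 0.1), 10)
TRIPLET_AXIS = np.round(np.arange(-1.5, 2.5 + 0.02, 0.04), 10)


def hyperplane_pair(
    vectorA: np.ndarray,
    vectorB: np.ndarray,
    evaluator,
    threshold: float = VALIDITY_THRESHOLD,
) -> HyperplaneResult:
    """Nine convex interpolants w·A + (1−w)·B, w ∈ {0.1, …, 0.9}.

    The pair counts as connected iff every interpolant is valid.
    """
    A = np.asarray(vectorA, dtype=float)
    B = np.asarray(vectorB, dtype=float)
    if A.shape != B.shape:
        raise ValueError("vectors must share one layout")
    P = np.array([float(evaluator(w * A + (1.0 - w) * B)) for w in PAIR_WEIGHTS])
    return HyperplaneResult(
        kind="pair", weights=PAIR_WEIGHTS.copy(), P=P, connected=bool(np.all(P < threshold))
    )


def hyperplane_triplet(
    vectorA: np.ndarray,
    vectorB: np.ndarray,
    vectorC: np.ndarray,
    evaluator,
) -> HyperplaneResult:
    """P over the (w₁, w₂) grid on the plane through three valid solutions.

    w₁, w₂ ∈ {−1.5, −1.46, …, 2.5} and w₃ = 1 − w₁ − w₂; grid points whose
    combination contains any negative parameter are masked out and carry no
    P (NaN).  Non-spiking points carry the evaluator's own sentinel (6).
    """
    A, B, C = (np.asarray(v, dtype=float) for v in (vectorA, vectorB, vectorC))
    if not (A.shape == B.shape == C.shape):
        raise ValueError("vectors must share one layout")
    W1, W2 = np.meshgrid(TRIPLET_AXIS, TRIPLET_AXIS, indexing="ij")
    # the uniform grid does not hit the unit-weight corners exactly, so the
    # three vertices are appended explicitly (vertex identity is part of the
    # contract: the inputs themselves must appear in the evaluated set)
    w1 = np.concatenate([W1.ravel(), [1.0, 0.0, 0.0]])
    w2 = np.concatenate([W2.ravel(), [0.0, 1.0, 0.0]])
    w3 = 1.0 - w1 - w2
    points = w1[:, None] * A + w2[:, None] * B + w3[:, None] * C
    masked = np.any(points < 0.0, axis=1)
    P = np.full(len(points), np.nan)
    for i in np.flatnonzero(~masked):
        P[i] = float(evaluator(points[i]))
    return HyperplaneResult(
        kind="triplet",
        weights=np.column_stack([w1, w2]),
        P=P,
        masked=masked,
    )


__all__ = [
    "wilson_ci",
    "PopulationConfig",
    "PopulationResult",
    "sample_population",
    "classify_population",
    "range_sweep",
    "pairwise_correlations",
    "mean_offdiagonal_r",
    "WalkResult",
    "random_walk",
    "walk_ensemble",
    "ExpansionResult",
    "expand_isoforms",
    "HyperplaneResult",
    "PAIR_WEIGHTS",
    "TRIPLET_AXIS",
    "hyperplane_pair",
    "hyperplane_triplet",
]
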