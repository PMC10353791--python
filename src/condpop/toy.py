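"""Probabilistic toy model: the law-of-large-numbers view of degeneracy.

Each model parameter is a random variable on [0, 2]; the model "output" is
the mean of the variables, and a sample is *valid* when that mean lies
within 0.015 of the target value 1 (strict inequality).  With more
independent variables the mean concentrates (law of large numbers), so the
valid fraction grows with n — the toy analogue of more ion channels making
valid conductance combinations more frequent.

Variants: a Gaussian copula imposes pairwise correlation ρ on the uniform
marginals; a "distributed" largest-gap sampler anti-correlates the
variables; nonlinear interaction orders pass the variables through
column-normalised random interaction matrices and an elementwise sigmoid.
An exact Irwin–Hall oracle provides the analytic valid fraction for the
independent case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

DEFAULT_TOL = 0.015
DEFAULT_RANGE = (0.0, 2.0)
TARGET = 1.0


@dataclass(frozen=True)
class ToyConfig:
    n_vars: int
    n_samples: int
    lo: float = 0.0
    hi: float = 2.0
    target: float = TARGET
    tolerance: float = DEFAULT_TOL
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("need lo < hi")
        if self.tolerance <= 0.0:
            raise ValueError("tolerance must be positive")


# --------------------------------------------------------------------------
# samplers
# --------------------------------------------------------------------------

def sample_independent(config: ToyConfig) -> np.ndarray:
    """i.i.d. uniform samples on [lo, hi], shape (n_samples, n_vars)."""
    rng = np.random.default_rng(config.rng_seed)
    return rng.uniform(config.lo, config.hi, size=(config.n_samples, config.n_vars))


def copula_correlation_matrix(n_vars: int, rho: float) -> np.ndarray:
    """Equicorrelation matrix R (R_ij = ρ off-diagonal), validated PSD.

    An equicorrelation matrix is positive semidefinite iff
    ρ ≥ −1/(n−1) (and ρ ≤ 1), which is why an arbitrary pairwise *negative*
    correlation cannot be specified in high dimension.
    """
    if n_vars >= 2 and not (-1.0 / (n_vars - 1) - 1e-12 <= rho < 1.0):
        raise ValueError(
            f"equicorrelation with rho={rho} is not positive semidefinite for "
            f"n={n_vars}; need rho >= -1/(n-1) = {-1.0 / (n_vars - 1):.4f}"
        )
    R = np.full((n_vars, n_vars), rho)
    np.fill_diagonal(R, 1.0)
    return R


def sample_copula(n_vars: int, rho: float, n_samples: int, seed: int = 0) -> np.ndarray:
    """Gaussian-copula sample with uniform marginals on [0, 2].

    A latent Gaussian vector z ~ N(0, R) with equicorrelation ρ is mapped
    through the standard normal CDF to uniform marginals on [0, 1] and
    scaled by 2.  The resulting uniforms have Pearson correlation
    (6/π)·arcsin(ρ/2).
    """
    R = copula_correlation_matrix(n_vars, rho)
    rng = np.random.default_rng(seed)
    # eigen decomposition handles the PSD boundary (rho = -1/(n-1)) gracefully
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    z = rng.standard_normal(size=(n_samples, n_vars)) @ L.T
    return 2.0 * stats.norm.cdf(z)


@njit(cache=True)
def _distributed_rows(n_samples, n_vars, unif):
    """Largest-gap insertion; ``unif`` supplies U(0,1) draws row-major."""
    out = np.empty((n_samples, n_vars))
    vals = np.empty(n_vars + 2)
    for s in range(n_samples):
        k = 0
        x1 = 2.0 * unif[s, 0]
        out[s, 0] = x1
        # sorted existing values with the interval bounds 0 and 2
        vals[0] = 0.0
        vals[1] = x1
        vals[2] = 2.0
        n_vals = 3
        for k in range(1, n_vars):
            # find the largest gap; ties broken by the lowest left endpoint
            best_i = 0
            best_gap = -1.0
            for i in range(n_vals - 1):
                gap = vals[i + 1] - vals[i]
                if gap > best_gap:
                    best_gap = gap
                    best_i = i
            lo = vals[best_i]
            hi = vals[best_i + 1]
            x = lo + (hi - lo) * unif[s, k]
            out[s, k] = x
            # insert x keeping vals sorted
            j = n_vals
            while j > 0 and vals[j - 1] > x:
                vals[j] = vals[j - 1]
                j -= 1
            vals[j] = x
            n_vals += 1
    return out


def sample_distributed(n_vars: int, n_samples: int, seed: int = 0) -> np.ndarray:
    """'Distributed' sampler: each new variable lands in the largest gap.

    The first variable is uniform on [0, 2]; every subsequent variable is
    uniform on the largest interval between the ordered existing variables
    (boundary gaps [0, min] and [max, 2] included).  Row sums concentrate
    near n, so row means concentrate near 1 — tighter than independence.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    rng = np.random.default_rng(seed)
    unif = rng.random((n_samples, n_vars))
    return _distributed_rows(n_samples, n_vars, unif)


# --------------------------------------------------------------------------
# validity
# --------------------------------------------------------------------------

def valid_mask(matrix: np.ndarray, target: float = TARGET, tol: float = DEFAULT_TOL) -> np.ndarray:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    return np.abs(matrix.mean(axis=1) - target) < tol


def valid_fraction(matrix: np.ndarray, target: float = TARGET, tol: float = DEFAULT_TOL) -> float:
    """Fraction of rows whose mean is strictly within ``tol`` of ``target``."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.size == 0:
        raise ValueError("empty sample matrix")
    return float(valid_mask(matrix, target, tol).mean())


def prefix_valid_fractions(
    n_max: int, n_samples: int, seed: int = 0, tol: float = DEFAULT_TOL
) -> np.ndarray:
    """Valid fraction for every n = 1 … n_max using common random numbers.

    One (n_samples × n_max) uniform matrix is drawn and the fraction for n
    uses its first n columns, so adjacent fractions share their samples.
    The coupling cancels most Monte Carlo noise from the *comparison* across
    n (the classic common-random-numbers variance reduction), making the
    increase of the valid fraction with n visible at moderate sample sizes.
    """
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.0, 2.0, size=(n_samples, n_max))
    csum = np.cumsum(m, axis=1)
    ns = np.arange(1, n_max + 1)
    means = csum / ns
    return np.asarray((np.abs(means - TARGET) < tol).mean(axis=0))


def analytic_valid_fraction(n_vars: int, tol: float = DEFAULT_TOL) -> float:
    """Exact P(|mean of n i.i.d. U(0,2) − 1| < tol) via the Irwin–Hall law.

    The mean of n U(0,2) variables is (2/n)·S with S ~ IrwinHall(n), so the
    probability equals F(n/2 + n·tol/2) − F(n/2 − n·tol/2).
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    ih = stats.irwinhall(n_vars)
    half = n_vars * tol / 2.0
    mid = n_vars / 2.0
    return float(ih.cdf(mid + half) - ih.cdf(mid - half))


# --------------------------------------------------------------------------
# nonlinear interaction orders
# --------------------------------------------------------------------------

def sigmoid(x: np.ndarray) -> np.ndarray:
    """S(x) = −1 + 2/(1 + e^(−x)), the elementwise squashing onto (−1, 1)."""
    return -1.0 + 2.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class NonlinearConfig:
    """Interaction order and the two left-stochastic interaction matrices."""

    order: int
    M: np.ndarray | None = None
    M_hat: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")


def random_interaction_matrix(n_vars: int, rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
    """n×n matrix, entries uniform on [−1, 1], columns normalised to sum 1.

    A column whose raw sum is too close to zero would explode under
    normalisation; such columns are redrawn.
    """
    M = rng.uniform(-1.0, 1.0, size=(n_vars, n_vars))
    for j in range(n_vars):
        tries = 0
        while abs(M[:, j].sum()) < 1e-3:
            M[:, j] = rng.uniform(-1.0, 1.0, size=n_vars)
            tries += 1
            if tries > max_tries:
                raise RuntimeError("could not draw a normalisable column")
        M[:, j] /= M[:, j].sum()
    return M


def make_nonlinear_config(n_vars: int, order: int, seed: int = 0) -> NonlinearConfig:
    rng = np.random.default_rng(seed)
    M = random_interaction_matrix(n_vars, rng) if order >= 1 else None
    M_hat = random_interaction_matrix(n_vars, rng) if order >= 2 else None
    return NonlinearConfig(order=order, M=M, M_hat=M_hat)


def nonlinear_transform(u: np.ndarray, config: NonlinearConfig) -> np.ndarray:
    """v₀ = S(u); v₁ = S(M·S(u)); v₂ = S(M̂·S(M·S(u))). Rows are samples."""
    u = np.asarray(u, dtype=float)
    v = sigmoid(u)
    if config.order >= 1:
        v = sigmoid(v @ config.M.T)
    if config.order >= 2:
        v = sigmoid(v @ config.M_hat.T)
    return v


def nonlinear_valid_fraction(
    n_vars: int,
    order: int,
    n_samples: int,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
) -> float:
    """Valid fraction for one interaction order and one matrix draw.

    Validity keeps the distance-to-target semantics of the linear toy model:
    the reference output is the transform of the all-ones vector (the
    deterministic target configuration) under the same matrices, and a
    sample is valid iff |mean(v) − mean(v_ref)| < tol.
    """
    cfg = make_nonlinear_config(n_vars, order, seed=seed)
    rng = np.random.default_rng(seed + 1)
    u = rng.uniform(0.0, 2.0, size=(n_samples, n_vars))
    v = nonlinear_transform(u, cfg)
    v_ref = nonlinear_transform(np.ones((1, n_vars)), cfg)
    return float((np.abs(v.mean(axis=1) - v_ref.mean()) < tol).mean())


# --------------------------------------------------------------------------
# summaries and experiments
# --------------------------------------------------------------------------

def output_correlation_summary(valid_rows: np.ndarray) -> float:
    """Mean pairwise Pearson r over the columns of the valid rows.

    Degenerate (constant) columns are excluded from the average.
    """
    valid_rows = np.asarray(valid_rows, dtype=float)
    if valid_rows.ndim != 2 or valid_rows.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two columns")
    if valid_rows.shape[0] < 3:
        raise ValueError("need at least 3 valid rows")
    sd = valid_rows.std(axis=0)
    keep = sd > 0.0
    if keep.sum() < 2:
        return math.nan
    C = np.corrcoef(valid_rows[:, keep], rowvar=False)
    iu = np.triu_indices_from(C, k=1)
    return float(np.mean(C[iu]))


def range_shrink_experiment(
    n_vars_list,
    half_widths=None,
    tol: float = DEFAULT_TOL,
    n_samples: int = 100_000,
    seed: int = 0,
):
    """Valid fraction per (n_vars, half-width) with sampling on [1−w, 1+w].

    ``half_widths`` defaults to 1.0 down to 0.1 in steps of 0.1 — shrinking
    the sampling range around the target mean.
    """
    import pandas as pd

    if half_widths is None:
        half_widths = [round(1.0 - 0.1 * i, 10) for i in range(10)]
    rows = []
    for n_vars in n_vars_list:
        for i, w in enumerate(half_widths):
            if not (0.0 < w <= 1.0):
                raise ValueError("half-widths must lie in (0, 1]")
            cfg = ToyConfig(
                n_vars=n_vars,
                n_samples=n_samples,
                lo=1.0 - w,
                hi=1.0 + w,
                tolerance=tol,
                rng_seed=seed + 1000 * n_vars + i,
            )
            frac = valid_fraction(sample_independent(cfg), tol=tol)
            rows.append({"n_vars": n_vars, "half_width": w, "fraction": frac})
    return pd.DataFrame(rows)


__all__ = [
    "DEFAULT_TOL",
    "TARGET",
    "ToyConfig",
    "NonlinearConfig",
    "sample_independent",
    "sample_copula",
    "sample_distributed",
    "copula_correlation_matrix",
    "valid_mask",
    "valid_fraction",
    "prefix_valid_fractions",
    "analytic_valid_fraction",
    "sigmoid",
    "random_interaction_matrix",
    "make_nonlinear_config",
    "nonlinear_transform",
    "nonlinear_valid_fraction",
    "output_correlation_summary",
    "range_shrink_experiment",
]
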