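"""Step 1 — force-recruitment-threshold distribution and mapping to the pool.

The recruitment thresholds of a motoneuron pool of N units are modelled by a
linear-exponential distribution

    F^th(j) = k1 · (k2 · j/N + Δ_F^((j/N)^k3)),   j ∈ [1..N]

fitted to a literature-derived step partition of the pool into 10 %MVC bins,
with the boundary values F^th(1) and F^th(N) = Δ_F · F^th(1) as heavily
weighted constraints.  Identified units are then assigned pool locations N_i
by inverting the fitted distribution at their recorded thresholds.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ThresholdDistribution",
    "PoolMap",
    "ta_step_distribution",
    "step_function_from_bins",
    "fit_threshold_distribution",
    "evaluate_fth",
    "map_to_pool",
    "TA_FTH_COEFFS",
]

# Fitted TA coefficients (k1 %MVC, k2, k3) with Δ_F = 120, as used throughout
# for the tibialis anterior (and reused for gastrocnemius medialis).
TA_FTH_COEFFS = (0.50, 58.12, 1.83)
TA_DELTA_F = 120.0


@dataclass(frozen=True)
class ThresholdDistribution:
    k1: float
    k2: float
    k3: float
    delta_f: float
    n_pool: int

    def __post_init__(self) -> None:
        if self.delta_f <= 1:
            raise ValueError("delta_f must exceed 1")
        if self.n_pool < 2:
            raise ValueError("n_pool must be at least 2")
        f = self(np.arange(1, self.n_pool + 1))
        if np.any(np.diff(f) <= 0) or f[0] <= 0:
            raise ValueError("threshold distribution must be positive and strictly increasing")

    def __call__(self, j):
        return evaluate_fth(self, j)


@dataclass(frozen=True)
class PoolMap:
    """Assignment of identified MNs (i, ordered by threshold) to pool indices N_i."""

    assignments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ns = [n for _, n in self.assignments]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("pool locations N_i must be strictly increasing with i")

    @property
    def locations(self) -> np.ndarray:
        return np.array([n for _, n in self.assignments], dtype=int)

    def __len__(self) -> int:
        return len(self.assignments)


def ta_step_distribution() -> pd.DataFrame:
    """Packaged TA pool partition into 10 %MVC recruitment-threshold bins."""
    with importlib.resources.files("monpool.data").joinpath("ta_fth_bins.csv").open() as fh:
        return pd.read_csv(fh)


def step_function_from_bins(bins: pd.DataFrame, n_pool: int) -> tuple[np.ndarray, np.ndarray]:
    """Map bin fractions to per-index threshold targets.

    Returns (j, fth_target) where each pool index j is assigned the midpoint
    of its 10 %MVC bin, following the cumulative bin fractions.
    """
    frac = bins["fraction"].to_numpy(dtype=float)
    if abs(frac.sum() - 1.0) > 1e-6:
        raise ValueError("bin fractions must sum to 1")
    if (frac > 0).sum() < 2:
        raise ValueError("step distribution needs at least two occupied bins")
    edges = np.concatenate([[0], np.round(np.cumsum(frac) * n_pool).astype(int)])
    j = np.arange(1, n_pool + 1)
    target = np.empty(n_pool)
    mids = (bins["bin_low"].to_numpy(float) + bins["bin_high"].to_numpy(float)) / 2.0
    for lo, hi, mid in zip(edges[:-1], edges[1:], mids):
        target[lo:hi] = mid
    return j, target


def fit_threshold_distribution(
    bins: pd.DataFrame,
    n_pool: int,
    delta_f: float = TA_DELTA_F,
    fth_first: float = 0.75,
    fth_last: float | None = None,
    boundary_weight: float = 100.0,
) -> ThresholdDistribution:
    """Least-squares fit of the linear-exponential distribution to step data.

    The boundary targets F^th(1)=fth_first and F^th(N)=fth_last (by default
    Δ_F·fth_first) enter the fit as points weighted ``boundary_weight`` times
    a bin point.
    """
    if fth_last is None:
        fth_last = delta_f * fth_first
    j, target = step_function_from_bins(bins, n_pool)
    x = np.concatenate([j / n_pool, [1.0 / n_pool, 1.0]])
    y = np.concatenate([target, [fth_first, fth_last]])
    w = np.concatenate([np.ones(j.size), [boundary_weight, boundary_weight]])

    def model(x, k1, k2, k3):
        return k1 * (k2 * x + delta_f ** (x**k3))

    p0 = (fth_first / 2.0, 50.0, 2.0)
    popt, _ = optimize.curve_fit(
        model, x, y, p0=p0, sigma=1.0 / np.sqrt(w), absolute_sigma=False, maxfev=20000,
        bounds=([1e-6, 0.0, 0.2], [np.inf, np.inf, 10.0]),
    )
    dist = ThresholdDistribution(k1=float(popt[0]), k2=float(popt[1]), k3=float(popt[2]),
                                 delta_f=float(delta_f), n_pool=int(n_pool))
    return dist


def evaluate_fth(dist: ThresholdDistribution, j) -> np.ndarray | float:
    """Evaluate F^th(j) (%MVC) at integer or fractional pool indices."""
    jj = np.asarray(j, dtype=float)
    x = jj / dist.n_pool
    out = dist.k1 * (dist.k2 * x + dist.delta_f ** (x**dist.k3))
    return float(out) if np.isscalar(j) else out


def map_to_pool(thresholds: Sequence[float], dist: ThresholdDistribution) -> PoolMap:
    """Assign pool locations N_i by inverting F^th at the recorded thresholds.

    Thresholds must be sorted ascending.  Values below F^th(1) clamp to 1 with
    a warning; duplicates receive consecutive increasing locations.
    """
    th = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(th) < 0):
        raise ValueError("thresholds must be sorted in ascending order")
    n = dist.n_pool
    f1, fn = evaluate_fth(dist, 1), evaluate_fth(dist, n)
    assignments: list[tuple[int, int]] = []
    prev = 0
    for i, t in enumerate(th, start=1):
        if t > fn * (1 + 1e-9):
            raise ValueError(f"MN {i}: threshold {t:.3g} %MVC exceeds F^th(N) = {fn:.3g} %MVC")
        if t <= f1:
            warnings.warn(f"MN {i}: threshold {t:.3g} %MVC below F^th(1); clamped to pool index 1")
            ni = 1
        else:
            x = optimize.brentq(lambda jj: evaluate_fth(dist, jj) - t, 1.0, float(n), xtol=1e-9)
            ni = int(round(x))
        ni = max(ni, prev + 1)  # keep the map injective and order-preserving
        if ni > n:
            raise ValueError("pool exhausted while resolving duplicate thresholds")
        assignments.append((i, ni))
        prev = ni
    return PoolMap(tuple(assignments))
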