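"""Motor-unit Hill-type muscle stage: spike trains → active states → force.

Each motor unit converts its spike train into an active state a_j(t) through
a two-stage excitation–contraction coupling model: a normalized calcium
concentration c(t) receives a saturating increment at each discharge and
decays first-order, and the calcium–troponin complex b(t) follows first-order
binding/unbinding driven by c.  The active state is a saturating (Michaelis–
Menten-like) function of b.  At optimal length with force–velocity, tendon
and passive elements neglected, the unit force is f_j = f_iso^max(j)·a_j and
the whole-muscle force is the linear sum Σ_j f_j.  The rate constants are
modelling choices (≈50 ms twitch rise, fusion approached near 100 Hz), not
measured values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .spiketrain import ContractionProtocol, DriveSignal, SpikeTrain

__all__ = ["MuscleUnitParams", "ActivationTrace", "mu_force_distribution",
           "activation_dynamics", "tetanic_asymptote", "simulate_muscle",
           "simulate_muscle_pool"]


@dataclass(frozen=True)
class MuscleUnitParams:
    fiso_max: float = 1.0  # maximal isometric tetanic force (arbitrary or N)
    calcium_gain: float = 0.35  # saturating fractional Ca increment per discharge
    calcium_decay_s: float = 0.060  # Ca removal time constant (s)
    binding_rate: float = 40.0  # Ca–troponin binding rate constant (1/s)
    unbinding_rate: float = 10.0  # Ca–troponin unbinding rate constant (1/s)
    shape_k: float = 0.20  # half-saturation shape of the activation nonlinearity

    def __post_init__(self) -> None:
        if not (0 < self.calcium_gain < 1):
            raise ValueError("calcium_gain must lie in (0, 1)")
        if min(self.fiso_max, self.calcium_decay_s, self.binding_rate,
               self.unbinding_rate, self.shape_k) <= 0:
            raise ValueError("all unit parameters must be positive")


@dataclass(frozen=True)
class ActivationTrace:
    times: np.ndarray
    a: np.ndarray  # active state in [0, 1]
    calcium: np.ndarray
    bound: np.ndarray


def mu_force_distribution(n_pool: int, fold_range: float = 100.0,
                          total: float = 1.0) -> np.ndarray:
    """Exponential distribution of unit tetanic forces across the pool.

    f(j) ∝ fold_range^((j−1)/(N−1)); strictly increasing with the recruitment
    index and normalized so Σ f = ``total``.
    """
    if n_pool < 1:
        raise ValueError("n_pool must be positive")
    if fold_range < 1:
        raise ValueError("fold_range must be at least 1")
    j = np.arange(n_pool, dtype=float)
    f = fold_range ** (j / max(n_pool - 1, 1))
    return f / f.sum() * total


@njit(cache=True)
def _activation_loop(spike_flags, dt, gain, tau_c, kon, koff):  # pragma: no cover
    n = spike_flags.size
    c_out = np.empty(n)
    b_out = np.empty(n)
    c = 0.0
    b = 0.0
    decay = np.exp(-dt / tau_c)
    for i in range(n):
        if spike_flags[i]:
            c = c + gain * (1.0 - c)
        rate = kon * c + koff
        b_inf = kon * c / rate
        b = b_inf + (b - b_inf) * np.exp(-rate * dt)
        c_out[i] = c
        b_out[i] = b
        c *= decay
    return c_out, b_out


def _saturating(b: np.ndarray, k: float) -> np.ndarray:
    return b * (1.0 + k) / (b + k)


def activation_dynamics(train: SpikeTrain, params: MuscleUnitParams = MuscleUnitParams(),
                        dt: float = 1e-3, t_span: tuple[float, float] | None = None
                        ) -> ActivationTrace:
    """Integrate the excitation–contraction stages for one unit."""
    if dt > 1e-3:
        raise ValueError("dt must not exceed 0.001 s")
    if t_span is None:
        t_hi = train.firing_times[-1] + 5 * params.calcium_decay_s if train.n_spikes else 1.0
        t_span = (0.0, float(t_hi))
    n = int(np.floor((t_span[1] - t_span[0]) / dt)) + 1
    t = t_span[0] + np.arange(n) * dt
    flags = np.zeros(n, dtype=np.bool_)
    if train.n_spikes:
        idx = np.round((train.firing_times - t_span[0]) / dt).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        flags[idx] = True
    c, b = _activation_loop(flags, dt, params.calcium_gain, params.calcium_decay_s,
                            params.binding_rate, params.unbinding_rate)
    return ActivationTrace(times=t, a=_saturating(b, params.shape_k), calcium=c, bound=b)


def tetanic_asymptote(params: MuscleUnitParams = MuscleUnitParams()) -> float:
    """Active-state limit for infinitely fast stimulation (c → 1)."""
    b_inf = params.binding_rate / (params.binding_rate + params.unbinding_rate)
    return float(_saturating(np.asarray(b_inf), params.shape_k))


def simulate_muscle(trains: Sequence[SpikeTrain], unit_params: Sequence[MuscleUnitParams],
                    protocol: ContractionProtocol, dt: float = 1e-3) -> DriveSignal:
    """Whole-muscle force as the linear sum of unit forces f_iso^max(j)·a_j(t)."""
    if len(trains) != len(unit_params):
        raise ValueError("one parameter set per train is required")
    t_span = (protocol.t_tr[0], protocol.t_tr[5])
    n = int(np.floor((t_span[1] - t_span[0]) / dt)) + 1
    total = np.zeros(n)
    times = t_span[0] + np.arange(n) * dt
    for tr, p in zip(trains, unit_params):
        act = activation_dynamics(tr, p, dt=dt, t_span=t_span)
        total += p.fiso_max * act.a
    return DriveSignal(times, total, role="force")


def simulate_muscle_pool(trains: Sequence[SpikeTrain], protocol: ContractionProtocol,
                         fold_range: float = 100.0, pool_locations: Sequence[int] | None = None,
                         n_pool: int | None = None, dt: float = 1e-3,
                         base_params: MuscleUnitParams = MuscleUnitParams()) -> DriveSignal:
    """Convenience wrapper: assign tetanic forces across the pool and sum forces.

    ``pool_locations`` gives each train's index in a pool of ``n_pool`` units,
    so a subsample can be scaled with the same f_iso^max(j) distribution as a
    full pool; by default trains are assumed to be the full pool 1..N.
    """
    n = len(trains)
    if pool_locations is None:
        pool_locations = np.arange(1, n + 1)
        n_pool = n_pool or n
    if n_pool is None:
        raise ValueError("n_pool is required when pool_locations are given")
    fdist = mu_force_distribution(n_pool, fold_range)
    params = [MuscleUnitParams(fiso_max=float(fdist[int(j) - 1]),
                               calcium_gain=base_params.calcium_gain,
                               calcium_decay_s=base_params.calcium_decay_s,
                               binding_rate=base_params.binding_rate,
                               unbinding_rate=base_params.unbinding_rate,
                               shape_k=base_params.shape_k)
              for j in pool_locations]
    return simulate_muscle(trains, params, protocol, dt=dt)
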