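"""Single-compartment leaky integrate-and-fire motoneuron, size-parameterized.

All electrophysiological parameters derive from the membrane surface area S:

    R = k_R / S^2.43        input resistance (size principle: bigger ⇒ leakier)
    C = C_m · S             membrane capacitance
    τ = R · C               membrane time constant
    I^th = ΔV_th / R        rheobase (Ohm's law)

The membrane charges as a capacitor and fires when V_m reaches ΔV_th, after
which it is held at rest for the inert period IP (optionally randomized per
spike, sd = IP/10), which caps the firing rate at ≈ 1/IP.  During the
derecruitment phase of a contraction the apparent resistance is raised to
R^d = R/k^dth (hysteresis: units stop firing at lower current than they were
recruited at) and the specific capacitance to C_m^d (lower rates near
derecruitment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .spiketrain import SpikeTrain

__all__ = [
    "DVTH",
    "CM",
    "KR_DEFAULT",
    "LifParameters",
    "DerecruitmentParams",
    "params_from_size",
    "simulate",
    "steady_state_rate",
    "derecruitment_variant",
]

DVTH = 0.027  # V, relative voltage threshold ΔV_th
CM = 1.3e-2  # F/m², specific membrane capacitance (1.3 μF/cm²)
SIZE_EXPONENT = 2.43

# k_R anchors R at a mid-range reference size: (S_ref, R_ref) = (2.5e-7 m², 2 MΩ)
KR_DEFAULT = 2.0e6 * (2.5e-7) ** SIZE_EXPONENT

_SIZE_BOUNDS = (5e-8, 1e-6)  # m², sanity range for mammalian alpha-MN somata+dendrites


@dataclass(frozen=True)
class LifParameters:
    size_s: float  # m²
    kr: float
    cm: float
    dvth: float
    ip: float  # s

    def __post_init__(self) -> None:
        if not (_SIZE_BOUNDS[0] < self.size_s < _SIZE_BOUNDS[1]):
            raise ValueError(f"size {self.size_s:.3g} m² outside the physiological range {_SIZE_BOUNDS}")
        if min(self.kr, self.cm, self.dvth, self.ip) <= 0:
            raise ValueError("kr, cm, dvth and ip must be positive")

    @property
    def resistance_r(self) -> float:
        return self.kr / self.size_s**SIZE_EXPONENT

    @property
    def capacitance_c(self) -> float:
        return self.cm * self.size_s

    @property
    def tau(self) -> float:
        return self.resistance_r * self.capacitance_c

    @property
    def rheobase(self) -> float:
        return self.dvth / self.resistance_r


@dataclass(frozen=True)
class DerecruitmentParams:
    """Apparent-parameter switch applied from ``switch_time`` (t_tr3) onwards."""

    kth_ratio: float  # I^dth / I^th, in (0, 1)
    cmd: float  # F/m², apparent specific capacitance during derecruitment
    switch_time: float  # s

    def __post_init__(self) -> None:
        if not (0.0 < self.kth_ratio < 1.0):
            raise ValueError("kth_ratio must lie strictly in (0, 1)")
        if self.cmd < CM * 0.999:
            raise ValueError("derecruitment C_m^d must not fall below C_m")


def params_from_size(size_s: float, kr: float = KR_DEFAULT, cm: float = CM,
                     dvth: float = DVTH, ip: float = 0.04) -> LifParameters:
    return LifParameters(size_s=size_s, kr=kr, cm=cm, dvth=dvth, ip=ip)


def derecruitment_variant(params: LifParameters, kth_ratio: float, cmd: float,
                          switch_time: float) -> DerecruitmentParams:
    """Derecruitment-phase parameters: R^d = R/k ⇒ I^dth = k·I^th < I^th."""
    return DerecruitmentParams(kth_ratio=kth_ratio, cmd=cmd, switch_time=switch_time)


@njit(cache=True)
def _lif_loop(i_samples, dt, r1, tau1, r2, tau2, switch_idx, dvth, ip,
              ip_sd, noise):  # pragma: no cover - exercised through simulate()
    n = i_samples.size
    spikes = np.empty(n, dtype=np.float64)
    n_spikes = 0
    vm = 0.0
    refractory_until = -1.0
    k = 0
    a1 = np.exp(-dt / tau1)
    b1 = r1 * dt / tau1
    a2 = np.exp(-dt / tau2)
    b2 = r2 * dt / tau2
    for idx in range(1, n):
        t = idx * dt
        if t < refractory_until:
            vm = 0.0
            continue
        if idx < switch_idx:
            vm = a1 * vm + b1 * i_samples[idx]
        else:
            vm = a2 * vm + b2 * i_samples[idx]
        if vm >= dvth:
            spikes[n_spikes] = t
            n_spikes += 1
            vm = 0.0
            hold = ip
            if ip_sd > 0.0:
                o = noise[k % noise.size] * ip_sd
                k += 1
                if o < -ip:
                    o = -ip
                hold = ip + o
            refractory_until = t + hold
    return spikes[:n_spikes]


@njit(cache=True)
def _lif_loop_exact(i_samples, dt, r1, tau1, dvth, ip):  # pragma: no cover
    """Exact exponential-integrator variant (coefficient R(1−e^{−dt/τ}))."""
    n = i_samples.size
    spikes = np.empty(n, dtype=np.float64)
    n_spikes = 0
    vm = 0.0
    refractory_until = -1.0
    a1 = np.exp(-dt / tau1)
    b1 = r1 * (1.0 - a1)
    for idx in range(1, n):
        t = idx * dt
        if t < refractory_until:
            vm = 0.0
            continue
        vm = a1 * vm + b1 * i_samples[idx]
        if vm >= dvth:
            spikes[n_spikes] = t
            n_spikes += 1
            vm = 0.0
            refractory_until = t + ip
    return spikes[:n_spikes]


def simulate(params: LifParameters, current, dt: float = 1e-4, *,
             derecruit: DerecruitmentParams | None = None,
             ip_noise: bool = False, seed: int | None = None,
             t_start: float | None = None, t_stop: float | None = None,
             mn_id: int = 0, scheme: str = "printed") -> SpikeTrain:
    """Integrate the LIF recurrence against a current input and return spikes.

    ``current`` is a DriveSignal (role=current) or any object with ``times`` /
    ``values``; it is resampled onto the dt grid by linear interpolation.
    Spike times are reported at the grid sample where threshold is crossed.
    """
    if dt > 1e-3:
        raise ValueError("dt must not exceed 0.001 s")
    t0 = current.times[0] if t_start is None else max(t_start, current.times[0])
    t1 = current.times[-1] if t_stop is None else min(t_stop, current.times[-1])
    n = int(np.floor((t1 - t0) / dt)) + 1
    tt = t0 + np.arange(n) * dt
    i_samples = np.interp(tt, current.times, current.values)

    r = params.resistance_r
    tau = params.tau
    if derecruit is not None:
        r2 = r / derecruit.kth_ratio
        tau2 = r2 * derecruit.cmd * params.size_s
        switch_idx = int(np.ceil((derecruit.switch_time - t0) / dt))
        switch_idx = max(0, min(switch_idx, n))
    else:
        r2, tau2, switch_idx = r, tau, n + 1

    if scheme == "exact":
        rel = _lif_loop_exact(i_samples, dt, r, tau, params.dvth, params.ip)
    else:
        if ip_noise:
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(4096)
            ip_sd = params.ip / 10.0
        else:
            noise = np.zeros(1)
            ip_sd = 0.0
        rel = _lif_loop(i_samples, dt, r, tau, r2, tau2, switch_idx,
                        params.dvth, params.ip, ip_sd, noise)
    return SpikeTrain(mn_id=mn_id, firing_times=t0 + rel, sampling_rate=1.0 / dt)


def steady_state_rate(params: LifParameters, i_const: float) -> float:
    """Closed-form steady firing rate under constant supra-threshold current.

    FF(I) = 1 / (IP − R·C·ln(1 − ΔV_th/(R·I))); diverges to 0 at rheobase and
    saturates at 1/IP for large I.
    """
    if i_const <= params.rheobase:
        raise ValueError("steady_state_rate requires a supra-threshold current")
    r = params.resistance_r
    return 1.0 / (params.ip - r * params.capacitance_c * np.log(1.0 - params.dvth / (r * i_const)))
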