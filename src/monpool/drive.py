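"""Step 2 — common synaptic input, representativeness checks, current input.

The effective neural drive carried by a sample of identified spike trains is
estimated as the [0;10] Hz low-passed cumulative spike train (the common
synaptic input, CSI, in arbitrary units); the common synaptic control (CSC)
is the CSI further low-passed to [0;4] Hz.  Whether the identified sample is
large and representative enough for the pool's linearity property to hold is
assessed by (a) intra-sample coherence between complementary half-samples and
(b) agreement of the normalized CSC with the normalized force trace.

The CSI is scaled to a physical current input I(t) by anchoring it, at the
first discharges of the lowest- and highest-threshold identified units, to a
literature rheobase distribution I^th(j) = I_min · Δ_I^((j/N)^c).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .mapping import PoolMap
from .spiketrain import (ContractionProtocol, DriveSignal, SpikeTrain, compare,
                         cumulative_spike_train, lowpass)

__all__ = [
    "RheobaseDistribution",
    "CoherenceReport",
    "CurrentInput",
    "estimate_common_input",
    "coherence_representativeness",
    "rheobase_distribution",
    "build_current_input",
]


@dataclass(frozen=True)
class RheobaseDistribution:
    i_min: float = 3.9e-9  # A, rheobase of the smallest unit
    delta_i: float = 9.1  # fold range across the pool
    exponent: float = 1.18
    n_pool: int = 400

    def __post_init__(self) -> None:
        if self.i_min <= 0 or self.delta_i <= 1 or self.exponent <= 0:
            raise ValueError("rheobase distribution requires i_min>0, delta_i>1, exponent>0")

    def __call__(self, j):
        return rheobase_distribution(j, self)


def rheobase_distribution(j, params: RheobaseDistribution):
    """I^th(j) in amperes at pool index j (scalar or vector)."""
    jj = np.asarray(j, dtype=float)
    out = params.i_min * params.delta_i ** ((jj / params.n_pool) ** params.exponent)
    return float(out) if np.isscalar(j) else out


@dataclass(frozen=True)
class CoherenceReport:
    half_sample_mean: float
    extrapolated_full: float
    csc_force_r2: float
    csc_force_nrmse: float
    representative: bool


@dataclass(frozen=True)
class CurrentInput:
    signal: DriveSignal  # role="current", amperes
    gain: float  # A per CSI unit
    onset_time: float  # first discharge of the lowest-threshold identified MN
    anchors: tuple[float, float]  # (I^th_{N1}, I^th_{Nr}) in A

    @property
    def times(self) -> np.ndarray:
        return self.signal.times

    @property
    def values(self) -> np.ndarray:
        return self.signal.values

    def value_at(self, t: float) -> float:
        return self.signal.value_at(t)


def estimate_common_input(trains: Sequence[SpikeTrain], protocol: ContractionProtocol,
                          csi_cutoff_hz: float = 10.0, csc_cutoff_hz: float = 4.0):
    """CSI and CSC from the identified trains.

    Returns ``(csi, csc, csi_norm, csc_norm)``: the raw low-passed cumulative
    spike trains and their peak-normalized versions.
    """
    if len(trains) < 1:
        raise ValueError("estimate_common_input needs at least one train")
    cst = cumulative_spike_train(trains, protocol)
    csi = lowpass(cst, csi_cutoff_hz, role="CSI")
    csc = lowpass(csi, csc_cutoff_hz, role="CSC")
    return csi, csc, csi.normalized(), csc.normalized()


def _coherence_band_mean(x: np.ndarray, y: np.ndarray, fs: float,
                         band: tuple[float, float] = (1.0, 10.0)) -> float:
    nperseg = min(int(round(fs)), x.size)  # 1 s Hann segments, 50% overlap
    f, cxy = sps.coherence(x, y, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.mean(cxy[sel]))


def _composite_coherence(k: float, gamma: float) -> float:
    return k * gamma / (1.0 + (k - 1.0) * gamma)


def coherence_representativeness(trains: Sequence[SpikeTrain], force: DriveSignal,
                                 protocol: ContractionProtocol, n_perm: int = 20,
                                 seed: int | None = 0,
                                 csc: DriveSignal | None = None) -> CoherenceReport:
    """Half-sample coherence check of sample representativeness.

    For ``n_perm`` random permutations the sample is split into complementary
    halves; the magnitude-squared coherence between the two half cumulative
    spike trains is averaged over [1;10] Hz.  The mean half-sample coherence
    is extrapolated to the full sample size by inverting the composite
    coherence relation C_k = kγ/(1+(k−1)γ) at k = N_r/2 (an analytic stand-in
    for the published figure lookup).  Representativeness additionally
    requires the normalized CSC to track the normalized force trace.
    """
    nr = len(trains)
    if nr < 4:
        raise ValueError("coherence check requires at least 4 identified trains")
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate
    vals = []
    for _ in range(n_perm):
        idx = rng.permutation(nr)
        if nr % 2:
            idx = idx[:-1]  # odd sample: drop one train at random this permutation
        half = idx.size // 2
        cst1 = cumulative_spike_train([trains[i] for i in idx[:half]], protocol)
        cst2 = cumulative_spike_train([trains[i] for i in idx[half:]], protocol)
        vals.append(_coherence_band_mean(cst1.values, cst2.values, fs))
    half_mean = float(np.mean(vals))
    k = nr // 2
    gamma = half_mean / (k - (k - 1) * half_mean) if half_mean < 1.0 else 1.0
    gamma = min(max(gamma, 0.0), 1.0)
    coher_full = _composite_coherence(nr, gamma)

    if csc is None:
        _, _, _, csc = estimate_common_input(trains, protocol)
    m = compare(csc.normalized(), force.normalized())
    representative = (coher_full > 0.7) and (m.r2 > 0.7) and (m.nrmse < 30.0)
    return CoherenceReport(half_sample_mean=half_mean, extrapolated_full=float(coher_full),
                           csc_force_r2=m.r2, csc_force_nrmse=m.nrmse,
                           representative=bool(representative))


def build_current_input(csi: DriveSignal, pool_map: PoolMap, rheo: RheobaseDistribution,
                        trains: Sequence[SpikeTrain]) -> CurrentInput:
    """Anchored-affine scaling of the CSI to a current input I(t).

    I(t) = 0 before the first identified discharge; afterwards
    I(t) = I^th_{N1} + G · (CSI(t) − CSI(ft¹_{N1})) with G chosen so that
    I(ft¹_{Nr}) = I^th_{Nr}.  Both anchors hold exactly for any CSI
    normalization, reducing to the plain affine form when CSI is zero at onset.
    """
    if len(trains) != len(pool_map):
        raise ValueError("one train per mapped MN is required")
    first = trains[0]
    last = trains[-1]
    if first.n_spikes == 0 or last.n_spikes == 0:
        raise ValueError("first and last identified MNs must each have at least one discharge")
    t_on = first.first_discharge
    t_last = last.first_discharge
    locs = pool_map.locations
    i_lo = rheobase_distribution(int(locs[0]), rheo)
    i_hi = rheobase_distribution(int(locs[-1]), rheo)
    c_on = csi.value_at(t_on)
    c_last = csi.value_at(t_last)
    denom = c_last - c_on
    if abs(denom) < 1e-12 * max(abs(c_last), 1.0):
        raise ValueError(
            "CSI is flat between the first discharges of the lowest- and highest-threshold "
            "identified MNs; a larger or better-spread sample is needed to scale the current"
        )
    gain = (i_hi - i_lo) / denom
    values = i_lo + gain * (csi.values - c_on)
    values[csi.times < t_on] = 0.0
    sig = DriveSignal(csi.times, values, role="current")
    return CurrentInput(signal=sig, gain=float(gain), onset_time=float(t_on),
                        anchors=(float(i_lo), float(i_hi)))
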