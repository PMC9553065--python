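"""Spike-train representations and the signal operations shared by the workflow.

The whole pipeline lives on a uniform time grid (the HDEMG sampling grid,
2048 Hz by default) so that binarization of discharge times is lossless to one
sample.  Rates are expressed in Hz, times in seconds, forces in %MVC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "ContractionProtocol",
    "SpikeTrain",
    "RateSeries",
    "DriveSignal",
    "ValidationMetrics",
    "binarize",
    "instantaneous_discharge_frequency",
    "filtered_idf",
    "polynomial_trend",
    "cumulative_spike_train",
    "lowpass",
    "compare",
]


@dataclass(frozen=True)
class ContractionProtocol:
    """Trapezoidal isometric contraction protocol.

    ``t_tr`` holds the six times (s) delimiting rest / up-ramp / plateau /
    down-ramp / rest; ``plateau_mvc`` is the target force plateau in %MVC.
    """

    t_tr: tuple[float, float, float, float, float, float]
    plateau_mvc: float
    sampling_rate: float = 2048.0

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.t_tr)
        if len(t) != 6:
            raise ValueError("t_tr must contain six times t_tr0..t_tr5")
        if any(b < a for a, b in zip(t, t[1:])):
            raise ValueError("t_tr must be non-decreasing")
        if not (0.0 < self.plateau_mvc <= 100.0):
            raise ValueError("plateau_mvc must lie in (0, 100]")
        object.__setattr__(self, "t_tr", t)

    @property
    def duration(self) -> float:
        return self.t_tr[5] - self.t_tr[0]

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration * self.sampling_rate)) + 1
        return self.t_tr[0] + np.arange(n) / self.sampling_rate

    def force_trace(self) -> "DriveSignal":
        """Idealized trapezoid force trace (%MVC) implied by the protocol."""
        t = self.time_grid()
        return DriveSignal(t, self.plateau_mvc * trapezoid_shape(t, self.t_tr), role="force")


def trapezoid_shape(t: np.ndarray, t_tr: Sequence[float]) -> np.ndarray:
    """Unit-plateau trapezoid: 0 at rest, linear ramps, 1 on the plateau."""
    t0, t1, t2, t3, t4, _ = t_tr
    up = np.clip((t - t1) / max(t2 - t1, 1e-12), 0.0, 1.0)
    down = np.clip((t4 - t) / max(t4 - t3, 1e-12), 0.0, 1.0) if t4 > t3 else (t <= t3).astype(float)
    return np.minimum(up, down)


@dataclass(frozen=True)
class SpikeTrain:
    """Discharge times of one motoneuron.

    ``recruitment_threshold`` is the force level (%MVC) at which the unit was
    recruited, when recorded.
    """

    mn_id: int
    firing_times: np.ndarray
    recruitment_threshold: float | None = None
    sampling_rate: float = 2048.0

    def __post_init__(self) -> None:
        ft = np.asarray(self.firing_times, dtype=float)
        if ft.ndim != 1:
            raise ValueError("firing_times must be one-dimensional")
        if ft.size and (np.any(np.diff(ft) <= 0) or ft[0] < 0):
            raise ValueError("firing_times must be strictly increasing and non-negative")
        th = self.recruitment_threshold
        if th is not None and not (0.0 < th <= 100.0):
            raise ValueError("recruitment_threshold must lie in (0, 100] %MVC")
        object.__setattr__(self, "firing_times", ft)

    @property
    def n_spikes(self) -> int:
        return int(self.firing_times.size)

    @property
    def first_discharge(self) -> float:
        if not self.firing_times.size:
            raise ValueError(f"MN {self.mn_id} has no discharges")
        return float(self.firing_times[0])

    @property
    def last_discharge(self) -> float:
        if not self.firing_times.size:
            raise ValueError(f"MN {self.mn_id} has no discharges")
        return float(self.firing_times[-1])


@dataclass(frozen=True)
class RateSeries:
    """Uniformly sampled discharge-rate series (IDF impulses, FIDF or trend)."""

    times: np.ndarray
    values: np.ndarray
    kind: Literal["IDF-impulse", "FIDF", "trend"]
    valid: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must share a shape")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class DriveSignal:
    """Uniformly sampled drive-type signal (CST, CSI, CSC, eND, current, force)."""

    times: np.ndarray
    values: np.ndarray
    role: Literal["CST", "eND", "CSI", "CSC", "current", "force", "binary"] = "CST"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(v)):
            raise ValueError("signal values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])

    def normalized(self) -> "DriveSignal":
        peak = float(np.max(np.abs(self.values)))
        if peak == 0.0:
            return self
        return DriveSignal(self.times, self.values / peak, role=self.role)

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))


@dataclass(frozen=True)
class ValidationMetrics:
    """Agreement metrics between two signals.

    nRMSE and nME are expressed as % of the reference-signal range; r² is the
    coefficient of determination (1 − SS_res/SS_tot); dft1 is the signed error
    (s) in predicted recruitment time, where applicable.
    """

    nrmse: float
    r2: float
    nme: float
    dft1: float | None = None


# ---------------------------------------------------------------------------
# operations


def binarize(train: SpikeTrain, protocol: ContractionProtocol, *, merge_coincident: bool = False) -> DriveSignal:
    """Binary spike train on the protocol grid: 1 at the sample nearest each discharge."""
    t = protocol.time_grid()
    values = np.zeros_like(t)
    ft = train.firing_times
    if ft.size:
        if ft[0] < protocol.t_tr[0] - 0.5 / protocol.sampling_rate or ft[-1] > protocol.t_tr[5] + 0.5 / protocol.sampling_rate:
            raise ValueError(
                f"MN {train.mn_id}: firing times outside the protocol window "
                f"[{protocol.t_tr[0]}, {protocol.t_tr[5]}] s"
            )
        idx = np.round((ft - protocol.t_tr[0]) * protocol.sampling_rate).astype(int)
        idx = np.clip(idx, 0, t.size - 1)
        if np.unique(idx).size != idx.size:
            if not merge_coincident:
                raise ValueError(
                    f"MN {train.mn_id}: two discharges fall on the same grid sample "
                    f"(physiologically impossible at {protocol.sampling_rate:g} Hz); "
                    "pass merge_coincident=True to merge them"
                )
            warnings.warn(f"MN {train.mn_id}: coincident discharges merged into one sample")
            idx = np.unique(idx)
        values[idx] = 1.0
    return DriveSignal(t, values, role="binary")


def instantaneous_discharge_frequency(train: SpikeTrain, protocol: ContractionProtocol) -> RateSeries:
    """Impulse train of instantaneous discharge frequencies.

    At the grid sample nearest each discharge ft_k (except the last), the value
    is the reciprocal inter-spike interval 1/(ft_{k+1} − ft_k); zero elsewhere.
    A train with fewer than two discharges yields an empty, flagged series.
    """
    t = protocol.time_grid()
    values = np.zeros_like(t)
    ft = train.firing_times
    if ft.size < 2:
        return RateSeries(t, values, kind="IDF-impulse", valid=False)
    rates = 1.0 / np.diff(ft)
    idx = np.round((ft[:-1] - protocol.t_tr[0]) * protocol.sampling_rate).astype(int)
    idx = np.clip(idx, 0, t.size - 1)
    values[idx] = rates
    return RateSeries(t, values, kind="IDF-impulse", valid=True)


def hann_window(window_s: float, sampling_rate: float) -> np.ndarray:
    n = int(round(window_s * sampling_rate))
    if n < 2:
        raise ValueError("smoothing window must span at least 2 grid steps")
    return sps.windows.hann(n, sym=True)


def filtered_idf(idf: RateSeries, window_s: float = 0.400) -> RateSeries:
    """Smoothed discharge frequency (FIDF): Hanning moving average of the IDF.

    Implemented as a kernel-weighted moving average of the discharge-rate
    values (ratio of two Hanning convolutions), so that a periodic train maps
    to its rate and the output keeps frequency units.
    """
    if idf.kind != "IDF-impulse":
        raise ValueError("filtered_idf expects an IDF-impulse series")
    w = hann_window(window_s, idf.sampling_rate)
    if not idf.valid or not np.any(idf.values):
        return RateSeries(idf.times, np.zeros_like(idf.values), kind="FIDF", valid=idf.valid)
    mask = (idf.values > 0).astype(float)
    num = sps.fftconvolve(idf.values, w, mode="same")
    den = sps.fftconvolve(mask, w, mode="same")
    out = np.zeros_like(num)
    good = den > 1e-9
    out[good] = num[good] / den[good]
    return RateSeries(idf.times, np.maximum(out, 0.0), kind="FIDF", valid=True)


def polynomial_trend(idf: RateSeries, order: int = 6) -> RateSeries:
    """Least-squares polynomial trendline of the IDF values at firing instants.

    The polynomial is fitted to the (time, rate) pairs of the nonzero IDF
    samples only and evaluated across the firing span.  If fewer than
    ``order + 1`` pairs are available the order is reduced with a warning.
    """
    if idf.kind != "IDF-impulse":
        raise ValueError("polynomial_trend expects an IDF-impulse series")
    nz = np.nonzero(idf.values)[0]
    if nz.size < 2:
        return RateSeries(idf.times, np.zeros_like(idf.values), kind="trend", valid=False)
    tt, vv = idf.times[nz], idf.values[nz]
    eff_order = min(order, nz.size - 1)
    if eff_order < order:
        warnings.warn(f"polynomial trend order reduced from {order} to {eff_order} ({nz.size} firing samples)")
    # centre/scale the abscissa for conditioning
    t0, sc = tt.mean(), max(float(np.ptp(tt)) / 2.0, 1e-9)
    coeffs = np.polyfit((tt - t0) / sc, vv, eff_order)
    values = np.zeros_like(idf.values)
    span = slice(nz[0], nz[-1] + 1)
    values[span] = np.polyval(coeffs, (idf.times[span] - t0) / sc)
    return RateSeries(idf.times, values, kind="trend", valid=True)


def cumulative_spike_train(trains: Sequence[SpikeTrain], protocol: ContractionProtocol) -> DriveSignal:
    """Per-sample sum of the binarized spike trains (CST)."""
    if not trains:
        raise ValueError("cumulative_spike_train needs at least one train")
    total = np.zeros(protocol.time_grid().size)
    for tr in trains:
        total += binarize(tr, protocol).values
    return DriveSignal(protocol.time_grid(), total, role="CST")


def lowpass(sig: DriveSignal, cutoff_hz: float, order: int = 4, role: str | None = None) -> DriveSignal:
    """Zero-phase Butterworth low-pass filter (forward-backward, DC preserved)."""
    nyq = sig.sampling_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyq} Hz")
    sos = sps.butter(order, cutoff_hz / nyq, btype="low", output="sos")
    values = sps.sosfiltfilt(sos, sig.values)
    return DriveSignal(sig.times, values, role=role or sig.role)


def _overlap(a, b):
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if hi <= lo:
        raise ValueError("signals share no time support")
    ma = (a.times >= lo - 1e-12) & (a.times <= hi + 1e-12)
    av = a.values[ma]
    bv = np.interp(a.times[ma], b.times, b.values)
    return av, bv


def compare(a: DriveSignal | RateSeries, b: DriveSignal | RateSeries, dft1: float | None = None) -> ValidationMetrics:
    """nRMSE, r² and normalized maximum error of ``a`` against reference ``b``.

    nRMSE = RMS(a−b)/range(b)·100, nME = max|a−b|/range(b)·100 and
    r² = 1 − Σ(a−b)²/Σ(b−mean(b))², all restricted to the overlapping support.
    """
    av, bv = _overlap(a, b)
    rng = float(bv.max() - bv.min())
    if rng == 0.0:
        raise ValueError("reference signal has zero range")
    resid = av - bv
    nrmse = float(np.sqrt(np.mean(resid**2)) / rng * 100.0)
    nme = float(np.max(np.abs(resid)) / rng * 100.0)
    ss_tot = float(np.sum((bv - bv.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return ValidationMetrics(nrmse=nrmse, r2=r2, nme=nme, dft1=dft1)
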