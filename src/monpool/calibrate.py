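"""Step 3 — inert periods from saturation, size calibration, pool distributions.

Per identified unit: the polynomial trend of its discharge rate decides
whether it saturates during the force ramp; saturating units contribute
(N_i, IP_i = 1/max trend) pairs to a power fit IP(j) = a·j^b that assigns
inert periods to the whole pool.  Each unit's membrane surface area S_i is
then calibrated by matching the simulated to the experimental smoothed
discharge rate, and the pool size distribution S(j) = S_min·Δ_S^((j/N)^c)
is fitted to the calibrated (N_i, S_i) pairs.  Derecruitment-phase apparent
parameters (k^dth and C_m^d) are fitted on the down-ramp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from . import lif
from .drive import CurrentInput
from .spiketrain import (ContractionProtocol, RateSeries, SpikeTrain,
                         ValidationMetrics, compare, filtered_idf,
                         instantaneous_discharge_frequency, polynomial_trend)

__all__ = [
    "IpDistribution",
    "SizeDistribution",
    "detect_saturation",
    "fit_ip_distribution",
    "calibrate_size",
    "fit_size_distribution",
    "fit_derecruitment",
    "calibrate_cmd",
    "SIZE_BOUNDS_DEFAULT",
]

SIZE_BOUNDS_DEFAULT = (1.0e-7, 5.0e-7)  # m²


@dataclass(frozen=True)
class IpDistribution:
    """Power-law inert-period distribution IP(j) = a·j^b (seconds)."""

    a: float
    b: float
    pairs: tuple[tuple[int, float], ...] = ()

    def __call__(self, j):
        jj = np.asarray(j, dtype=float)
        out = self.a * jj**self.b
        return float(out) if np.isscalar(j) else out

    @property
    def max_rate_first_mn(self) -> float:
        """Maximum steady firing rate (Hz) of the lowest-threshold unit, 1/IP(1)."""
        return 1.0 / self(1)


@dataclass(frozen=True)
class SizeDistribution:
    """Power-family size distribution S(j) = s_min·Δ_S^((j/N)^c) (m²)."""

    s_min: float
    delta_s: float
    c: float
    n_pool: int

    def __call__(self, j):
        jj = np.asarray(j, dtype=float)
        out = self.s_min * self.delta_s ** ((jj / self.n_pool) ** self.c)
        return float(out) if np.isscalar(j) else out


def detect_saturation(idf_trend: RateSeries, protocol: ContractionProtocol
                      ) -> tuple[bool, float | None]:
    """Saturation test on a discharge-rate trendline.

    M is the mean trend over the plateau [t_tr2, t_tr3]; the unit saturates if
    the trend exceeds 0.9·M anywhere in [t_tr1, t_tr2 − 1 s] (i.e. it reached
    ≥90% of its plateau rate at least one second before the plateau).  The
    inert period of a saturating unit is 1/max(trend).
    """
    t = idf_trend.times
    _, t1, t2, t3, _, _ = protocol.t_tr
    plateau = (t >= t2) & (t <= t3) & (idf_trend.values > 0)
    if not np.any(plateau):
        raise ValueError("trend has no support on the force plateau")
    m = float(np.mean(idf_trend.values[plateau]))
    ramp = (t >= t1) & (t <= t2 - 1.0)
    saturating = bool(np.any(idf_trend.values[ramp] > 0.9 * m))
    if not saturating:
        return False, None
    return True, float(1.0 / np.max(idf_trend.values))


def fit_ip_distribution(pairs: Sequence[tuple[int, float]]) -> IpDistribution:
    """Log–log least-squares power fit IP(j) = a·j^b to (N_i, IP_i) pairs."""
    if len(pairs) < 2:
        raise ValueError(
            "at least two saturating units are required to fit IP(j); append auxiliary "
            "anchor pairs (e.g. from a better-sampled dataset) when the sample is sparse"
        )
    jj = np.array([p[0] for p in pairs], dtype=float)
    ip = np.array([p[1] for p in pairs], dtype=float)
    if np.any(jj <= 0) or np.any(ip <= 0):
        raise ValueError("pool indices and inert periods must be positive")
    slope, intercept = np.polyfit(np.log(jj), np.log(ip), 1)
    return IpDistribution(a=float(np.exp(intercept)), b=float(slope),
                          pairs=tuple((int(j), float(v)) for j, v in pairs))


def _simulated_fidf(size_s: float, ip: float, current: CurrentInput,
                    protocol: ContractionProtocol, dt: float,
                    derecruit: lif.DerecruitmentParams | None = None,
                    kr: float = lif.KR_DEFAULT, cm: float = lif.CM,
                    t_stop: float | None = None) -> tuple[RateSeries, SpikeTrain]:
    params = lif.params_from_size(size_s, kr=kr, cm=cm, ip=ip)
    train = lif.simulate(params, current.signal, dt=dt, derecruit=derecruit,
                         ip_noise=False, t_stop=t_stop)
    grid_train = SpikeTrain(mn_id=0, firing_times=train.firing_times,
                            sampling_rate=protocol.sampling_rate)
    idf = instantaneous_discharge_frequency(grid_train, protocol)
    return filtered_idf(idf), grid_train


def calibrate_size(target_fidf: RateSeries, ip: float, current: CurrentInput,
                   protocol: ContractionProtocol,
                   bounds: tuple[float, float] = SIZE_BOUNDS_DEFAULT,
                   dt: float = 1e-4, kr: float = lif.KR_DEFAULT,
                   target_train: SpikeTrain | None = None
                   ) -> tuple[float, float, ValidationMetrics]:
    """Calibrate the membrane surface area of one identified unit.

    Minimizes the RMS difference between simulated and experimental FIDF over
    [t_tr0, (t_tr2+t_tr3)/2] by bounded scalar (Brent) minimization; inert-
    period noise is off so the objective is deterministic.  Returns
    (S_i, J(S_i), metrics on [t_tr0, t_tr3]).
    """
    t0, _, t2, t3, _, _ = protocol.t_tr
    t_half = (t2 + t3) / 2.0
    win = (target_fidf.times >= t0) & (target_fidf.times <= t_half)
    target = target_fidf.values[win]
    t_end = protocol.t_tr[3]

    cache: dict[float, tuple] = {}

    def objective(s: float) -> float:
        fidf, train = _simulated_fidf(s, ip, current, protocol, dt, kr=kr, t_stop=t_end)
        cache[s] = (fidf, train)
        return float(np.sqrt(np.mean((fidf.values[win] - target) ** 2)))

    # no spikes even for the smallest (most excitable) size ⇒ unit unreachable
    objective(bounds[0])
    if cache[bounds[0]][1].n_spikes == 0:
        raise ValueError("unit produces no spikes at any admissible size under this current")
    res = optimize.minimize_scalar(objective, bounds=bounds, method="bounded",
                                   options={"xatol": bounds[0] * 1e-3})
    s_opt, j_opt = float(res.x), float(res.fun)
    if min(s_opt - bounds[0], bounds[1] - s_opt) < 0.01 * (bounds[1] - bounds[0]):
        warnings.warn(f"calibrated size {s_opt:.3g} m² sits at a bound; possible model misfit")
    fidf, train = cache.get(res.x, (None, None))
    if fidf is None:
        fidf, train = _simulated_fidf(s_opt, ip, current, protocol, dt, kr=kr, t_stop=t_end)
    mwin = (target_fidf.times >= t0) & (target_fidf.times <= t3)
    dft1 = None
    if target_train is not None and target_train.n_spikes and train.n_spikes:
        dft1 = train.first_discharge - target_train.first_discharge
    metrics = compare(
        RateSeries(target_fidf.times[mwin], fidf.values[mwin], kind="FIDF"),
        RateSeries(target_fidf.times[mwin], target_fidf.values[mwin], kind="FIDF"),
        dft1=dft1,
    )
    return s_opt, j_opt, metrics


def fit_size_distribution(pairs: Sequence[tuple[int, float]], delta_s: float = 2.4,
                          n_pool: int = 400) -> SizeDistribution:
    """Fit (s_min, c) of S(j) = s_min·Δ_S^((j/N)^c) with Δ_S held fixed."""
    if len(pairs) < 2:
        raise ValueError("at least two (N_i, S_i) pairs are required")
    jj = np.array([p[0] for p in pairs], dtype=float)
    ss = np.array([p[1] for p in pairs], dtype=float)
    x = jj / n_pool
    log_ds = np.log(delta_s)

    def model(x, log_smin, c):
        return log_smin + (x**c) * log_ds

    p0 = (np.log(ss.min()), 1.5)
    popt, _ = optimize.curve_fit(model, x, np.log(ss), p0=p0, maxfev=20000,
                                 bounds=([np.log(1e-9), 0.05], [np.log(1e-5), 10.0]))
    return SizeDistribution(s_min=float(np.exp(popt[0])), delta_s=float(delta_s),
                            c=float(popt[1]), n_pool=int(n_pool))


def fit_derecruitment(trains: Sequence[SpikeTrain], current: CurrentInput,
                      protocol: ContractionProtocol) -> float:
    """Zero-intercept slope of derecruitment vs recruitment current thresholds.

    Per unit, the recruitment current is I at its first discharge and the
    derecruitment current is I at its last discharge; k^dth is fitted by
    zero-intercept least squares and clipped below 1 with a warning.
    """
    rec, der = [], []
    for tr in trains:
        if tr.n_spikes < 2:
            continue
        if tr.last_discharge < protocol.t_tr[3]:
            continue  # unit must survive into the down-ramp
        rec.append(current.value_at(tr.first_discharge))
        der.append(current.value_at(tr.last_discharge))
    if not rec:
        raise ValueError("no unit has its last discharge within the derecruitment phase")
    rec, der = np.asarray(rec), np.asarray(der)
    k = float(np.sum(rec * der) / np.sum(rec * rec))
    if k >= 1.0:
        warnings.warn(f"fitted derecruitment ratio {k:.3f} ≥ 1; clipped to 0.999")
        k = 0.999
    return k


def calibrate_cmd(sizes: Sequence[float], ips: Sequence[float],
                  target_fidfs: Sequence[RateSeries], current: CurrentInput,
                  protocol: ContractionProtocol, kth_ratio: float,
                  grid_step: float = 0.1e-2, cmd_max: float = 3.0e-2,
                  dt: float = 1e-4, kr: float = lif.KR_DEFAULT) -> float:
    """Grid search for the apparent derecruitment specific capacitance C_m^d.

    For each candidate on the grid [C_m, cmd_max] (step 0.1 μF/cm²) all units
    are re-simulated over the derecruitment window [t_tr3, t_tr5] with
    R^d = R/k^dth, and the score J(C_m) = (mean nRMSE + 100·(1 − mean r²))/2
    is minimized.  Returns the arg-min; a boundary optimum yields a warning.
    """
    t3, t5 = protocol.t_tr[3], protocol.t_tr[5]
    grid = np.arange(lif.CM, cmd_max + grid_step / 2, grid_step)
    scores = []
    for cmd in grid:
        nrmses, r2s = [], []
        for s, ip, target in zip(sizes, ips, target_fidfs):
            der = lif.DerecruitmentParams(kth_ratio=kth_ratio, cmd=float(cmd), switch_time=t3)
            fidf, _ = _simulated_fidf(s, ip, current, protocol, dt, derecruit=der, kr=kr)
            win = (target.times >= t3) & (target.times <= t5)
            if not np.any(target.values[win] > 0):
                continue
            m = compare(RateSeries(target.times[win], fidf.values[win], kind="FIDF"),
                        RateSeries(target.times[win], target.values[win], kind="FIDF"))
            nrmses.append(m.nrmse)
            r2s.append(m.r2)
        if not nrmses:
            raise ValueError("no unit discharges in the derecruitment window")
        scores.append((np.mean(nrmses) + 100.0 * (1.0 - np.mean(r2s))) / 2.0)
    best = int(np.argmin(scores))
    if best in (0, len(grid) - 1) and len(grid) > 2:
        warnings.warn("C_m^d optimum at a grid boundary; score not parabolic on the grid")
    return float(grid[best])
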