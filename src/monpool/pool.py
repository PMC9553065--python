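"""Step 4 — simulate the reconstructed pool and validate its neural drive.

A cohort of N LIF models, scaled by the fitted size and inert-period
distributions and driven by the common current input, predicts the spike
trains of the complete pool.  The effective neural drive eND_N is the
[0;4] Hz low-passed cumulative spike train of the cohort, validated against
the normalized force trace.  Leave-one-out prediction of each identified
unit and a sensitivity sweep over the assumed pool size N are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import lif
from .calibrate import IpDistribution, SizeDistribution
from .drive import CurrentInput
from .spiketrain import (ContractionProtocol, DriveSignal, SpikeTrain,
                         ValidationMetrics, compare, cumulative_spike_train,
                         filtered_idf, instantaneous_discharge_frequency,
                         lowpass)

__all__ = ["PoolSpec", "PoolResult", "simulate_pool", "effective_neural_drive",
           "validate_against_force", "leave_one_out", "sensitivity_to_n"]


@dataclass(frozen=True)
class PoolSpec:
    n_pool: int
    size_dist: SizeDistribution
    ip_dist: IpDistribution
    derecruit_kth: float | None = None  # k^dth; None disables the derecruitment variant
    derecruit_cmd: float | None = None  # F/m²
    kr: float = lif.KR_DEFAULT
    ip_noise: bool = True
    master_seed: int = 0

    def mn_seed(self, j: int) -> int:
        # counter-based per-MN seeds: adding MNs never perturbs existing ones
        return (self.master_seed * 1_000_003 + j) % (2**31 - 1)


@dataclass(frozen=True)
class PoolResult:
    trains: tuple[SpikeTrain, ...]
    end_n: DriveSignal  # normalized eND_N
    cst: DriveSignal
    metrics: ValidationMetrics | None = None

    @property
    def n_pool(self) -> int:
        return len(self.trains)

    def firing_fraction(self) -> float:
        return float(np.mean([tr.n_spikes >= 2 for tr in self.trains]))

    def plateau_rates(self, protocol: ContractionProtocol) -> np.ndarray:
        """Mean smoothed discharge rate of each unit over the force plateau."""
        t2, t3 = protocol.t_tr[2], protocol.t_tr[3]
        rates = np.zeros(self.n_pool)
        for k, tr in enumerate(self.trains):
            if tr.n_spikes < 2:
                continue
            fidf = filtered_idf(instantaneous_discharge_frequency(tr, protocol))
            win = (fidf.times >= t2) & (fidf.times <= t3) & (fidf.values > 0)
            if np.any(win):
                rates[k] = float(np.mean(fidf.values[win]))
        return rates


def simulate_pool(spec: PoolSpec, current: CurrentInput,
                  protocol: ContractionProtocol, dt: float = 1e-4,
                  cutoff_hz: float = 4.0) -> PoolResult:
    """Simulate all N units of the reconstructed pool and compute eND_N."""
    trains = []
    t3 = protocol.t_tr[3]
    for j in range(1, spec.n_pool + 1):
        params = lif.params_from_size(float(spec.size_dist(j)), kr=spec.kr,
                                      ip=float(spec.ip_dist(j)))
        der = None
        if spec.derecruit_kth is not None and spec.derecruit_cmd is not None:
            der = lif.DerecruitmentParams(kth_ratio=spec.derecruit_kth,
                                          cmd=spec.derecruit_cmd, switch_time=t3)
        sim = lif.simulate(params, current.signal, dt=dt, derecruit=der,
                           ip_noise=spec.ip_noise, seed=spec.mn_seed(j), mn_id=j)
        trains.append(SpikeTrain(mn_id=j, firing_times=sim.firing_times,
                                 sampling_rate=protocol.sampling_rate))
    end_raw, end_norm = effective_neural_drive(trains, protocol, cutoff_hz=cutoff_hz)
    cst = cumulative_spike_train(trains, protocol)
    return PoolResult(trains=tuple(trains), end_n=end_norm, cst=cst)


def effective_neural_drive(trains: Sequence[SpikeTrain], protocol: ContractionProtocol,
                           cutoff_hz: float = 4.0) -> tuple[DriveSignal, DriveSignal]:
    """eND: low-passed cumulative spike train; returns (raw, peak-normalized)."""
    active = [tr for tr in trains if tr.n_spikes > 0]
    if not active:
        grid = protocol.time_grid()
        zero = DriveSignal(grid, np.zeros_like(grid), role="eND")
        return zero, zero
    cst = cumulative_spike_train(active, protocol)
    raw = lowpass(cst, cutoff_hz, role="eND")
    return raw, raw.normalized()


def validate_against_force(end: DriveSignal, force: DriveSignal) -> ValidationMetrics:
    """Compare normalized neural drive against the normalized force trace."""
    return compare(end.normalized(), force.normalized())


def leave_one_out(dataset, config=None) -> pd.DataFrame:
    """Blind per-unit validation: predict each identified unit from the rest.

    For each identified unit i, the current input and the IP(j)/S(j)
    distributions are rebuilt without train i; unit i is then simulated with
    the parameters read off the distributions at its pool location N_i, and
    its smoothed discharge rate is compared with the experimental one over
    the full protocol.  Returns a table (mn_id, N_i, dft1_s, nrmse, r2).
    """
    from .model import MotoneuronPool  # deferred: model builds on this module

    if dataset.n_identified < 3:
        raise ValueError("leave-one-out requires at least 3 identified trains")
    full = MotoneuronPool(dataset, config=config)
    full_fit = full.fit()
    locations = full_fit.pool_map.locations
    protocol = dataset.protocol
    rows = []
    for i in range(dataset.n_identified):
        reduced = dataset.drop(i)
        res = MotoneuronPool(reduced, config=full.config).fit()
        ni = int(locations[i])
        params = lif.params_from_size(float(res.size_dist(ni)), kr=full.config.kr,
                                      ip=float(res.ip_dist(ni)))
        der = lif.DerecruitmentParams(kth_ratio=res.derecruit_kth, cmd=res.derecruit_cmd,
                                      switch_time=protocol.t_tr[3])
        sim = lif.simulate(params, res.current.signal, dt=full.config.dt_s,
                           derecruit=der, ip_noise=False)
        sim_grid = SpikeTrain(mn_id=ni, firing_times=sim.firing_times,
                              sampling_rate=protocol.sampling_rate)
        exp = dataset.trains[i]
        fidf_sim = filtered_idf(instantaneous_discharge_frequency(sim_grid, protocol))
        fidf_exp = filtered_idf(instantaneous_discharge_frequency(exp, protocol))
        dft1 = (sim_grid.first_discharge - exp.first_discharge) if sim_grid.n_spikes else np.nan
        m = compare(fidf_sim, fidf_exp)
        rows.append({"mn_id": exp.mn_id, "N_i": ni, "dft1_s": dft1,
                     "nrmse": m.nrmse, "r2": m.r2})
    return pd.DataFrame(rows)


def sensitivity_to_n(dataset, n_values: Sequence[int], config=None) -> pd.DataFrame:
    """Rerun the full workflow for several assumed pool sizes N.

    Returns a table (N, r2, nrmse) of eND_N agreement with the force trace;
    the interest is the trend, not any fixed value.
    """
    from .model import MotoneuronPool

    rows = []
    for n in n_values:
        cfg = (config.replace(n_pool=int(n)) if config is not None else None)
        model = MotoneuronPool(dataset, config=cfg)
        if cfg is None:
            model = MotoneuronPool(dataset, config=model.config.replace(n_pool=int(n)))
        res = model.fit()
        pool_res = res.simulate_pool()
        m = validate_against_force(pool_res.end_n, dataset.force)
        rows.append({"N": int(n), "r2": m.r2, "nrmse": m.nrmse})
    return pd.DataFrame(rows)
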