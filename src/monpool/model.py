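"""Model/Results interface to the four-step pool-reconstruction workflow.

``MotoneuronPool`` is constructed from a dataset of identified spike trains
(with recruitment thresholds) plus a synchronized force trace, and ``fit()``
executes steps 1–3: map the identified units into the pool, estimate the
common synaptic input and scale it to a current, extract inert periods,
calibrate each unit's membrane surface area, and fit the pool-wide property
distributions.  The returned ``PoolReconstructionResults`` carries the fitted
distributions, per-unit diagnostics and a ``summary()`` table, and exposes
``simulate_pool()`` (step 4), ``leave_one_out()`` and ``predict_force()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibrate as cal
from . import lif
from .config import WorkflowConfig
from .dataset import Dataset, read_force, read_trains
from .drive import (CoherenceReport, CurrentInput, RheobaseDistribution,
                    build_current_input, coherence_representativeness,
                    estimate_common_input)
from .mapping import (PoolMap, ThresholdDistribution, fit_threshold_distribution,
                      map_to_pool, ta_step_distribution)
from .pool import (PoolResult, PoolSpec, simulate_pool, validate_against_force)
from .spiketrain import (ContractionProtocol, DriveSignal, RateSeries,
                         filtered_idf, instantaneous_discharge_frequency,
                         polynomial_trend)

__all__ = ["MotoneuronPool", "PoolReconstructionResults"]


class MotoneuronPool:
    """Motoneuron-pool reconstruction model.

    Parameters
    ----------
    data : Dataset
        Identified spike trains sorted by recruitment threshold, the
        synchronized whole-muscle force trace and the contraction protocol.
    config : WorkflowConfig, optional
        Workflow constants; defaults follow the published values.
    """

    def __init__(self, data: Dataset, config: WorkflowConfig | None = None):
        self.data = data
        self.config = config or WorkflowConfig()
        if self.data.n_identified < 2:
            raise ValueError("at least two identified trains are required")

    @classmethod
    def from_csv(cls, trains_path, thresholds_path, force_path,
                 protocol: ContractionProtocol,
                 config: WorkflowConfig | None = None) -> "MotoneuronPool":
        trains = read_trains(trains_path, thresholds_path,
                             sampling_rate=protocol.sampling_rate)
        force = read_force(force_path)
        return cls(Dataset(trains=tuple(trains), force=force, protocol=protocol), config)

    # -- steps -----------------------------------------------------------

    def _threshold_distribution(self) -> ThresholdDistribution:
        # The TA literature partition is also used for GM (no GM-specific
        # threshold data of sufficient size exists).
        bins = ta_step_distribution()
        return fit_threshold_distribution(bins, self.config.n_pool,
                                          delta_f=self.config.delta_f,
                                          fth_first=self.config.fth_first_mvc)

    def fit(self) -> "PoolReconstructionResults":
        cfg = self.config
        protocol = self.data.protocol
        trains = self.data.trains

        # step 1: map identified units into the pool
        fth_dist = self._threshold_distribution()
        pool_map = map_to_pool(self.data.thresholds, fth_dist)
        locations = pool_map.locations

        # step 2: common input, representativeness, current
        csi, csc, csi_n, csc_n = estimate_common_input(
            trains, protocol, cfg.csi_cutoff_hz, cfg.csc_cutoff_hz)
        coherence = coherence_representativeness(
            trains, self.data.force, protocol, n_perm=cfg.coherence_n_perm,
            seed=cfg.coherence_seed, csc=csc)
        if not coherence.representative:
            warnings.warn(
                "identified sample failed the representativeness check "
                f"(coher={coherence.extrapolated_full:.2f}, r2={coherence.csc_force_r2:.2f}, "
                f"nRMSE={coherence.csc_force_nrmse:.1f}%); proceeding regardless")
        rheo = RheobaseDistribution(i_min=cfg.i_min_a, delta_i=cfg.delta_i,
                                    exponent=cfg.rheobase_exponent, n_pool=cfg.n_pool)
        current = build_current_input(csi, pool_map, rheo, trains)

        # step 3a: inert periods from saturation
        fidfs, sat_flags, ip_pairs = [], [], list(cfg.ip_anchor_pairs)
        trends = []
        for tr, ni in zip(trains, locations):
            idf = instantaneous_discharge_frequency(tr, protocol)
            fidfs.append(filtered_idf(idf, cfg.fidf_window_s))
            trend = polynomial_trend(idf, cfg.trend_order)
            trends.append(trend)
            try:
                saturating, ip = cal.detect_saturation(trend, protocol)
            except ValueError:
                warnings.warn(f"MN {tr.mn_id}: no plateau discharge-rate support; "
                              "treated as non-saturating")
                saturating, ip = False, None
            sat_flags.append(saturating)
            if saturating:
                ip_pairs.append((int(ni), float(ip)))
        if len(ip_pairs) < 2:
            raise ValueError(
                "fewer than two saturating units: the IP distribution cannot be fitted; "
                "supply auxiliary anchor pairs via config.ip_anchor_pairs")
        ip_dist = cal.fit_ip_distribution(ip_pairs)
        ip_by_mn = {}
        for (tr, ni, sat) in zip(trains, locations, sat_flags):
            if sat:
                ip_by_mn[tr.mn_id] = next(v for j, v in ip_pairs if j == ni)
            else:
                ip_by_mn[tr.mn_id] = float(ip_dist(int(ni)))

        # step 3b: size calibration per unit
        sizes, costs, metrics = [], [], []
        for tr, ni, fidf in zip(trains, locations, fidfs):
            s_i, j_i, m = cal.calibrate_size(
                fidf, ip_by_mn[tr.mn_id], current, protocol,
                bounds=cfg.size_bounds_m2, dt=cfg.dt_s, kr=cfg.kr, target_train=tr)
            sizes.append(s_i)
            costs.append(j_i)
            metrics.append(m)
        size_dist = cal.fit_size_distribution(
            list(zip(locations.tolist(), sizes)), delta_s=cfg.delta_s, n_pool=cfg.n_pool)

        # step 3c: derecruitment-phase apparent parameters
        kth = cal.fit_derecruitment(trains, current, protocol)
        cmd = cal.calibrate_cmd(sizes, [ip_by_mn[tr.mn_id] for tr in trains], fidfs,
                                current, protocol, kth,
                                grid_step=cfg.cmd_grid_step_f_per_m2,
                                cmd_max=cfg.cmd_max_f_per_m2, dt=cfg.dt_s, kr=cfg.kr)

        per_mn = pd.DataFrame({
            "mn_id": [tr.mn_id for tr in trains],
            "fth_percent_mvc": self.data.thresholds,
            "N_i": locations,
            "saturating": sat_flags,
            "ip_s": [ip_by_mn[tr.mn_id] for tr in trains],
            "size_m2": sizes,
            "cost_hz": costs,
            "dft1_s": [m.dft1 for m in metrics],
            "nrmse": [m.nrmse for m in metrics],
            "r2": [m.r2 for m in metrics],
        })
        return PoolReconstructionResults(
            model=self, fth_dist=fth_dist, pool_map=pool_map, csi=csi, csc=csc,
            coherence=coherence, rheo=rheo, current=current, ip_dist=ip_dist,
            size_dist=size_dist, derecruit_kth=kth, derecruit_cmd=cmd,
            per_mn=per_mn, fidfs=tuple(fidfs), trends=tuple(trends))


@dataclass(frozen=True)
class PoolReconstructionResults:
    """Fitted distributions, per-unit diagnostics and pool-level predictions."""

    model: MotoneuronPool
    fth_dist: ThresholdDistribution
    pool_map: PoolMap
    csi: DriveSignal
    csc: DriveSignal
    coherence: CoherenceReport
    rheo: RheobaseDistribution
    current: CurrentInput
    ip_dist: cal.IpDistribution
    size_dist: cal.SizeDistribution
    derecruit_kth: float
    derecruit_cmd: float
    per_mn: pd.DataFrame
    fidfs: tuple[RateSeries, ...] = field(repr=False, default=())
    trends: tuple[RateSeries, ...] = field(repr=False, default=())

    # -- step 4 ----------------------------------------------------------

    def pool_spec(self, n_pool: int | None = None, seed: int | None = None,
                  ip_noise: bool | None = None) -> PoolSpec:
        cfg = self.model.config
        return PoolSpec(
            n_pool=n_pool or cfg.n_pool, size_dist=self.size_dist,
            ip_dist=self.ip_dist, derecruit_kth=self.derecruit_kth,
            derecruit_cmd=self.derecruit_cmd, kr=cfg.kr,
            ip_noise=cfg.ip_noise if ip_noise is None else ip_noise,
            master_seed=cfg.master_seed if seed is None else seed)

    def simulate_pool(self, n_pool: int | None = None, seed: int | None = None,
                      ip_noise: bool | None = None) -> PoolResult:
        spec = self.pool_spec(n_pool=n_pool, seed=seed, ip_noise=ip_noise)
        res = simulate_pool(spec, self.current, self.model.data.protocol,
                            dt=self.model.config.dt_s)
        m = validate_against_force(res.end_n, self.model.data.force)
        return PoolResult(trains=res.trains, end_n=res.end_n, cst=res.cst, metrics=m)

    def leave_one_out(self) -> pd.DataFrame:
        from .pool import leave_one_out
        return leave_one_out(self.model.data, self.model.config)

    def predict_force(self, pool_result: PoolResult | None = None, **muscle_kwargs):
        from .muscle import simulate_muscle_pool
        res = pool_result or self.simulate_pool()
        return simulate_muscle_pool(res.trains, self.model.data.protocol, **muscle_kwargs)

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        d = self.model.data
        locs = self.pool_map.locations
        lines = [
            "Motoneuron pool reconstruction",
            "=" * 62,
            f"Muscle: {cfg.muscle}    pool size N: {cfg.n_pool}    "
            f"identified N_r: {d.n_identified}",
            f"Identified locations N_i: {locs[0]}-{locs[-1]}",
            f"Threshold distribution F^th(j): k1={self.fth_dist.k1:.3g} %MVC, "
            f"k2={self.fth_dist.k2:.4g}, k3={self.fth_dist.k3:.3g}, "
            f"delta_F={self.fth_dist.delta_f:.0f}",
            f"Coherence (half-sample {self.coherence.half_sample_mean:.2f} -> "
            f"full {self.coherence.extrapolated_full:.2f}); "
            f"CSC vs force r2={self.coherence.csc_force_r2:.2f}, "
            f"nRMSE={self.coherence.csc_force_nrmse:.1f}% -> "
            f"{'representative' if self.coherence.representative else 'NOT representative'}",
            f"Current input: onset {self.current.onset_time:.2f} s, anchors "
            f"[{self.current.anchors[0]*1e9:.1f}, {self.current.anchors[1]*1e9:.1f}] nA, "
            f"gain {self.current.gain:.3g} A/unit",
            f"IP(j) = {self.ip_dist.a:.3g} * j^{self.ip_dist.b:.3g} s "
            f"({int(self.per_mn['saturating'].sum())}/{d.n_identified} saturating; "
            f"max rate of MN 1: {self.ip_dist.max_rate_first_mn:.1f} Hz)",
            f"S(j) = {self.size_dist.s_min:.3g} * {self.size_dist.delta_s:.2g}^"
            f"((j/{self.size_dist.n_pool})^{self.size_dist.c:.3g}) m^2",
            f"Derecruitment: k_th = {self.derecruit_kth:.3f}, "
            f"C_m^d = {self.derecruit_cmd*1e2:.2f} uF/cm^2",
            "-" * 62,
            "Per-unit calibration (FIDF agreement on [t_tr0, t_tr3]):",
            f"  median nRMSE {self.per_mn['nrmse'].median():.1f}%  "
            f"median r2 {self.per_mn['r2'].median():.2f}  "
            f"|dft1|<250 ms: {(self.per_mn['dft1_s'].abs() < 0.25).mean()*100:.0f}%",
        ]
        return "\n".join(lines)

    def plot_drive(self, ax=None):
        """Normalized CSI/CSC against the normalized force trace."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        f = self.model.data.force.normalized()
        ax.plot(f.times, f.values, label="force (norm.)", color="tab:green")
        csi_n = self.csi.normalized()
        csc_n = self.csc.normalized()
        ax.plot(csi_n.times, csi_n.values, label="CSI (norm.)", color="tab:red", alpha=0.7)
        ax.plot(csc_n.times, csc_n.values, label="CSC (norm.)", color="k", lw=1)
        ax.set_xlabel("time (s)")
        ax.legend()
        return ax

    def plot_distributions(self, axes=None):
        """Fitted S(j) and IP(j) with the calibrated per-unit points."""
        import matplotlib.pyplot as plt
        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        j = np.arange(1, self.model.config.n_pool + 1)
        axes[0].plot(j, self.size_dist(j), color="tab:red")
        axes[0].plot(self.per_mn["N_i"], self.per_mn["size_m2"], "kx")
        axes[0].set_xlabel("pool index j")
        axes[0].set_ylabel("S(j) (m$^2$)")
        axes[1].plot(j, self.ip_dist(j) * 1e3, color="tab:red")
        sat = self.per_mn[self.per_mn["saturating"]]
        axes[1].plot(sat["N_i"], sat["ip_s"] * 1e3, "kx")
        axes[1].set_xlabel("pool index j")
        axes[1].set_ylabel("IP(j) (ms)")
        return axes
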