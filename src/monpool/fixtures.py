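"""Synthetic ground-truth pools emulating the experimental datasets.

A fixture defines a full pool with size-principle-ordered properties, a
trapezoid common current drive, and a threshold-biased identified subsample
mimicking HDEMG decomposition's bias towards high-threshold units.  The
truth pool is built self-consistently from the rheobase distribution: with
R(j) = ΔV_th/I^th(j) and S(j) = (k_R/R(j))^(1/2.43), the size distribution
is exactly the power family S(j) = S_min·Δ_S^((j/N)^c) with
Δ_S = Δ_I^(1/2.43) ≈ 2.48 and c equal to the rheobase exponent.  This keeps
the generator's current scale commensurate with the estimation pipeline's
rheobase anchors, so recovery of the generating distributions is well-posed.

The truth drive realizes the trapezoidal *force* protocol (current warped
through the recruitment model, with seeded common fluctuation in [0;10] Hz),
and the fixture's "experimental force" is that drive passed through a 1 Hz
muscle-filtering low-pass and scaled to the plateau %MVC — for isometric
ramps the force tracks the common synaptic control, which is the premise
the workflow itself rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from . import lif
from .calibrate import IpDistribution, SizeDistribution
from .dataset import Dataset
from .drive import CurrentInput, RheobaseDistribution, rheobase_distribution
from .mapping import TA_DELTA_F, TA_FTH_COEFFS, ThresholdDistribution, evaluate_fth
from .pool import PoolResult, PoolSpec, simulate_pool
from .spiketrain import ContractionProtocol, DriveSignal, SpikeTrain, trapezoid_shape

__all__ = ["FixtureSpec", "generate_truth", "sample_identified",
           "identifiable", "make_reference_fixture", "make_dataset",
           "truth_force"]

SIZE_EXPONENT = lif.SIZE_EXPONENT


@dataclass(frozen=True)
class FixtureSpec:
    n_pool: int
    protocol: ContractionProtocol
    n_identified: int
    identification_bias: float = 2.0  # β: sampling weight ∝ (j/N)^β
    master_seed: int = 0
    threshold_jitter_mvc: float = 0.0
    drive_noise_rel: float = 0.10  # common-drive fluctuation, rel. sd in [0;10] Hz
    force_bandwidth_hz: float = 1.0  # muscle contractile filtering of the drive
    s_min: float = 1.49e-7  # m², smallest-unit surface area
    ip_a: float = 0.04  # s
    ip_b: float = 0.06
    i_min: float = 3.9e-9  # A
    delta_i: float = 9.1
    rheo_exponent: float = 1.18
    derecruit_kth: float = 0.9
    derecruit_cmd: float = 2.0e-2  # F/m² (2.0 μF/cm²)

    def __post_init__(self) -> None:
        if self.n_identified > self.n_pool:
            raise ValueError("n_identified cannot exceed n_pool")
        if self.identification_bias < 0:
            raise ValueError("identification bias must be non-negative")

    @property
    def fth_dist(self) -> ThresholdDistribution:
        k1, k2, k3 = TA_FTH_COEFFS
        return ThresholdDistribution(k1=k1, k2=k2, k3=k3, delta_f=TA_DELTA_F,
                                     n_pool=self.n_pool)

    @property
    def rheo_dist(self) -> RheobaseDistribution:
        return RheobaseDistribution(i_min=self.i_min, delta_i=self.delta_i,
                                    exponent=self.rheo_exponent, n_pool=self.n_pool)

    @property
    def kr(self) -> float:
        # anchor so that ΔV_th/R(S_min) equals the smallest rheobase
        return lif.DVTH * self.s_min**SIZE_EXPONENT / self.i_min

    @property
    def size_dist(self) -> SizeDistribution:
        return SizeDistribution(s_min=self.s_min,
                                delta_s=self.delta_i ** (1.0 / SIZE_EXPONENT),
                                c=self.rheo_exponent, n_pool=self.n_pool)

    @property
    def ip_dist(self) -> IpDistribution:
        return IpDistribution(a=self.ip_a, b=self.ip_b)


def _fth_inverse(spec: FixtureSpec, mvc) -> np.ndarray:
    """Pool index recruited at a given force level (fractional, clipped)."""
    fth = spec.fth_dist
    grid = np.arange(1, spec.n_pool + 1, dtype=float)
    fgrid = evaluate_fth(fth, grid)
    return np.interp(np.asarray(mvc, dtype=float), fgrid, grid)


def _truth_current(spec: FixtureSpec) -> CurrentInput:
    """Common current drive realizing the trapezoidal *force* protocol.

    The subject tracks a linear force ramp, so the current is warped through
    the recruitment model: at force level F the drive sits at the rheobase of
    the unit whose threshold is F, I(t) = I^th(F^th⁻¹(F(t))); unit j is thus
    recruited exactly when the force crosses its recruitment threshold.  Below
    the first unit's threshold the drive rises proportionally to force.  The
    plateau current therefore recruits exactly the pool fraction implied by
    the threshold distribution at the plateau %MVC."""
    fth = spec.fth_dist
    mvc = spec.protocol.plateau_mvc
    f1 = evaluate_fth(fth, 1.0)
    i1 = rheobase_distribution(1.0, spec.rheo_dist)
    t = spec.protocol.time_grid()
    shape = trapezoid_shape(t, spec.protocol.t_tr)
    force = mvc * shape
    if mvc <= f1:  # plateau below the first unit's threshold: silent pool
        i_plateau = i1 * mvc / f1
        values = i1 * force / f1
    else:
        if mvc >= evaluate_fth(fth, spec.n_pool):
            j_star = float(spec.n_pool)
        else:
            j_star = optimize.brentq(lambda j: evaluate_fth(fth, j) - mvc, 1.0,
                                     float(spec.n_pool))
        i_plateau = rheobase_distribution(j_star, spec.rheo_dist)
        values = np.where(
            force >= f1,
            rheobase_distribution(_fth_inverse(spec, np.maximum(force, f1)),
                                  spec.rheo_dist),
            i1 * force / f1,
        )
    if spec.drive_noise_rel > 0:
        # common synaptic input fluctuates in the [0;10] Hz band relevant for
        # force generation; the fluctuation scales with the drive level
        rng = np.random.default_rng(spec.master_seed + 777_000_001)
        white = rng.standard_normal(t.size)
        from .spiketrain import lowpass
        noisy = lowpass(DriveSignal(t, white), 10.0).values
        noisy /= max(np.std(noisy), 1e-12)
        values = values * (1.0 + spec.drive_noise_rel * noisy)
        values = np.maximum(values, 0.0)
    sig = DriveSignal(t, values, role="current")
    return CurrentInput(signal=sig, gain=float(i_plateau),
                        onset_time=spec.protocol.t_tr[1],
                        anchors=(0.0, float(i_plateau)))


def generate_truth(spec: FixtureSpec, dt: float = 1e-4
                   ) -> tuple[PoolSpec, CurrentInput, PoolResult]:
    """Simulate the ground-truth pool under the trapezoid drive."""
    pool_spec = PoolSpec(n_pool=spec.n_pool, size_dist=spec.size_dist,
                         ip_dist=spec.ip_dist, derecruit_kth=spec.derecruit_kth,
                         derecruit_cmd=spec.derecruit_cmd, kr=spec.kr,
                         ip_noise=True, master_seed=spec.master_seed)
    current = _truth_current(spec)
    result = simulate_pool(pool_spec, current, spec.protocol, dt=dt)
    return pool_spec, current, result


def identifiable(train: SpikeTrain, protocol: ContractionProtocol) -> bool:
    """Whether a unit's train could plausibly be identified by decomposition.

    Decomposition only separates units that discharge tonically through the
    plateau: at least 10 discharges overall, a mean plateau rate of ≥6 Hz
    (the minimum physiological tonic rate), and no silent plateau gap over
    0.5 s (intermittent, fluctuation-driven sources near the recruitment
    margin burst at drive peaks and cannot be separated reliably).
    """
    if train.n_spikes < 10:
        return False
    t2, t3 = protocol.t_tr[2], protocol.t_tr[3]
    plateau_s = max(t3 - t2, 1e-9)
    on_plateau = train.firing_times[(train.firing_times >= t2) & (train.firing_times <= t3)]
    if on_plateau.size / plateau_s < 6.0:
        return False
    return on_plateau.size >= 2 and float(np.max(np.diff(on_plateau))) <= 0.5


def sample_identified(spec: FixtureSpec, truth: PoolResult, seed: int | None = None
                      ) -> tuple[Dataset, np.ndarray]:
    """Threshold-biased subsample of the truth pool as an identified dataset.

    Unit j is drawn with probability ∝ (j/N)^β (without replacement) from the
    units with at least four discharges; recorded thresholds are the true
    F^th(j) plus optional Gaussian jitter.  Returns the dataset (trains
    renumbered 1..N_r in threshold order) and the true pool indices.
    """
    rng = np.random.default_rng(spec.master_seed if seed is None else seed)
    eligible = np.array([tr.mn_id for tr in truth.trains
                         if identifiable(tr, spec.protocol)])
    if eligible.size < spec.n_identified:
        raise ValueError(f"only {eligible.size} units fire enough to be identified")
    if spec.identification_bias > 0:
        w = (eligible / spec.n_pool) ** spec.identification_bias
    else:
        w = np.ones(eligible.size)
    chosen = rng.choice(eligible, size=spec.n_identified, replace=False, p=w / w.sum())
    chosen.sort()
    fth = spec.fth_dist
    trains = []
    for i, j in enumerate(chosen, start=1):
        th = float(evaluate_fth(fth, int(j)))
        if spec.threshold_jitter_mvc > 0:
            th = float(np.clip(th + rng.normal(0.0, spec.threshold_jitter_mvc),
                               1e-3, 100.0))
        src = truth.trains[int(j) - 1]
        trains.append(SpikeTrain(mn_id=i, firing_times=src.firing_times,
                                 recruitment_threshold=th,
                                 sampling_rate=spec.protocol.sampling_rate))
    order = np.argsort([tr.recruitment_threshold for tr in trains], kind="stable")
    trains = [replace(trains[k], mn_id=i + 1) for i, k in enumerate(order)]
    force = truth_force(spec)
    dataset = Dataset(trains=tuple(trains), force=force, protocol=spec.protocol)
    return dataset, chosen[order]


def truth_force(spec: FixtureSpec) -> DriveSignal:
    """Force proxy: the ground-truth drive filtered by the muscle's contractile
    low-pass and scaled to the plateau %MVC (isometric force tracks the common
    synaptic control; twitch dynamics suppress the drive's faster content)."""
    from .spiketrain import lowpass
    current = _truth_current(spec)
    filtered = lowpass(current.signal, spec.force_bandwidth_hz)
    vals = np.maximum(filtered.values, 0.0)
    peak = max(vals.max(), 1e-30)
    return DriveSignal(filtered.times, spec.protocol.plateau_mvc * vals / peak,
                       role="force")


_REFERENCE = {
    "DTA35-like": dict(n_pool=400, plateau=35.0, t_tr=(0.0, 2.2, 10.6, 20.5, 30.0, 30.0), n_identified=32),
    "HTA35-like": dict(n_pool=400, plateau=35.0, t_tr=(0.0, 2.1, 10.5, 20.5, 30.0, 33.0), n_identified=21),
    "HTA50-like": dict(n_pool=400, plateau=50.0, t_tr=(0.0, 1.6, 12.0, 21.8, 34.5, 35.0), n_identified=14),
    "HGM30-like": dict(n_pool=550, plateau=30.0, t_tr=(0.0, 3.1, 9.1, 28.0, 33.5, 107.0), n_identified=27),
}


def make_reference_fixture(name: str, master_seed: int = 0,
                           identification_bias: float = 2.0,
                           sampling_rate: float = 2048.0) -> FixtureSpec:
    """Fixture specs emulating the published dataset protocols."""
    if name not in _REFERENCE:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(_REFERENCE)}")
    ref = _REFERENCE[name]
    protocol = ContractionProtocol(t_tr=ref["t_tr"], plateau_mvc=ref["plateau"],
                                   sampling_rate=sampling_rate)
    return FixtureSpec(n_pool=ref["n_pool"], protocol=protocol,
                       n_identified=ref["n_identified"],
                       identification_bias=identification_bias,
                       master_seed=master_seed)


def make_dataset(spec: FixtureSpec, dt: float = 1e-4):
    """Generate truth and identified sample in one call.

    Returns (dataset, truth_info) where truth_info is a dict with the truth
    pool spec, current, pool result and the sampled units' true pool indices.
    """
    pool_spec, current, truth = generate_truth(spec, dt=dt)
    dataset, true_locations = sample_identified(spec, truth)
    return dataset, {"pool_spec": pool_spec, "current": current, "truth": truth,
                     "true_locations": true_locations, "fixture": spec}
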