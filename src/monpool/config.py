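"""Workflow configuration with the study's default constants.

Every default that has a published value keeps it: dt ≤ 0.001 s, ΔV_th 27 mV,
C_m 1.3 μF/cm², Δ_S 2.4, Δ_I 9.1, Δ_F 120, 400 ms smoothing window, 10/4 Hz
drive bands, 20 coherence permutations.  Keys carry unit suffixes.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from . import lif

__all__ = ["WorkflowConfig", "load_config"]


@dataclass(frozen=True)
class WorkflowConfig:
    muscle: str = "TA"
    n_pool: int = 400
    # threshold distribution
    delta_f: float = 120.0
    fth_first_mvc: float = 0.75
    # rheobase distribution
    i_min_a: float = 3.9e-9
    delta_i: float = 9.1
    rheobase_exponent: float = 1.18
    # LIF constants
    dvth_v: float = lif.DVTH
    cm_f_per_m2: float = lif.CM
    kr: float = lif.KR_DEFAULT
    dt_s: float = 1e-4
    # signal processing
    fidf_window_s: float = 0.400
    csi_cutoff_hz: float = 10.0
    csc_cutoff_hz: float = 4.0
    trend_order: int = 6
    # coherence check
    coherence_n_perm: int = 20
    coherence_seed: int = 0
    # calibration
    delta_s: float = 2.4
    size_bounds_m2: tuple[float, float] = (1.0e-7, 5.0e-7)
    cmd_grid_step_f_per_m2: float = 0.1e-2
    cmd_max_f_per_m2: float = 3.0e-2
    ip_anchor_pairs: tuple[tuple[int, float], ...] = ()
    # pool simulation
    ip_noise: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.muscle not in ("TA", "GM"):
            raise ValueError("muscle must be 'TA' or 'GM'")
        if self.dt_s > 1e-3:
            raise ValueError("dt_s must not exceed 0.001 s")
        if self.n_pool < 2:
            raise ValueError("n_pool must be at least 2")

    def replace(self, **kwargs) -> "WorkflowConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str) -> WorkflowConfig:
    """Read a TOML config file; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    names = {f.name for f in dataclasses.fields(WorkflowConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "size_bounds_m2" in raw:
        raw["size_bounds_m2"] = tuple(raw["size_bounds_m2"])
    if "ip_anchor_pairs" in raw:
        raw["ip_anchor_pairs"] = tuple((int(j), float(v)) for j, v in raw["ip_anchor_pairs"])
    return WorkflowConfig(**raw)
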