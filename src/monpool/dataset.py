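"""Experimental-style dataset container and its CSV readers/writers.

File formats (UTF-8, plain CSV):
  spike trains  — header ``mn_id,time_s``, one row per discharge;
  thresholds    — header ``mn_id,fth_percent_mvc``;
  force         — header ``time_s,force``.
Writers mirror readers bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spiketrain import ContractionProtocol, DriveSignal, SpikeTrain

__all__ = ["Dataset", "read_trains", "write_trains", "read_thresholds",
           "write_thresholds", "read_force", "write_force"]


@dataclass(frozen=True)
class Dataset:
    """Identified spike trains (sorted by recruitment threshold), force, protocol."""

    trains: tuple[SpikeTrain, ...]
    force: DriveSignal
    protocol: ContractionProtocol

    def __post_init__(self) -> None:
        ths = [tr.recruitment_threshold for tr in self.trains]
        if any(t is None for t in ths):
            raise ValueError("every identified train needs a recruitment threshold")
        if any(b < a for a, b in zip(ths, ths[1:])):
            raise ValueError("trains must be sorted by ascending recruitment threshold")

    @property
    def n_identified(self) -> int:
        return len(self.trains)

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([tr.recruitment_threshold for tr in self.trains], dtype=float)

    def drop(self, index: int) -> "Dataset":
        """Dataset without the ``index``-th train (for leave-one-out)."""
        kept = tuple(tr for k, tr in enumerate(self.trains) if k != index)
        return Dataset(trains=kept, force=self.force, protocol=self.protocol)


def read_trains(path, thresholds_path=None, sampling_rate: float = 2048.0) -> list[SpikeTrain]:
    df = pd.read_csv(path, float_precision="round_trip")
    th = None
    if thresholds_path is not None:
        tdf = pd.read_csv(thresholds_path, float_precision="round_trip")
        th = dict(zip(tdf["mn_id"].astype(int), tdf["fth_percent_mvc"].astype(float)))
    trains = []
    for mn_id, grp in df.groupby("mn_id", sort=True):
        trains.append(SpikeTrain(
            mn_id=int(mn_id),
            firing_times=np.sort(grp["time_s"].to_numpy(dtype=float)),
            recruitment_threshold=None if th is None else th.get(int(mn_id)),
            sampling_rate=sampling_rate,
        ))
    if th is not None:
        trains.sort(key=lambda tr: (tr.recruitment_threshold, tr.mn_id))
    return trains


def write_trains(trains: Sequence[SpikeTrain], path) -> None:
    rows = [(tr.mn_id, t) for tr in trains for t in tr.firing_times]
    pd.DataFrame(rows, columns=["mn_id", "time_s"]).to_csv(path, index=False, float_format="%.17g")


def read_thresholds(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_thresholds(trains: Sequence[SpikeTrain], path) -> None:
    rows = [(tr.mn_id, tr.recruitment_threshold) for tr in trains]
    pd.DataFrame(rows, columns=["mn_id", "fth_percent_mvc"]).to_csv(path, index=False, float_format="%.17g")


def read_force(path, sampling_rate: float | None = None) -> DriveSignal:
    df = pd.read_csv(path, float_precision="round_trip")
    return DriveSignal(df["time_s"].to_numpy(float), df["force"].to_numpy(float), role="force")


def write_force(force: DriveSignal, path) -> None:
    pd.DataFrame({"time_s": force.times, "force": force.values}).to_csv(path, index=False, float_format="%.17g")
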