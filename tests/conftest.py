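import warnings

import numpy as np
import pytest

from monpool import fixtures as fx
from monpool.model import MotoneuronPool
from monpool.spiketrain import ContractionProtocol, DriveSignal, SpikeTrain


@pytest.fixture(scope="session")
def short_protocol() -> ContractionProtocol:
    """A compact trapezoid protocol for unit-level tests."""
    return ContractionProtocol(t_tr=(0.0, 1.0, 4.0, 8.0, 10.0, 10.0), plateau_mvc=35.0)


@pytest.fixture(scope="session")
def dta35_spec():
    return fx.make_reference_fixture("DTA35-like", master_seed=1)


@pytest.fixture(scope="session")
def dta35_data(dta35_spec):
    """Ground truth + biased identified sample for the DTA35-like fixture."""
    return fx.make_dataset(dta35_spec)


@pytest.fixture(scope="session")
def dta35_results(dta35_data):
    """Full model fit (steps 1-3) on the DTA35-like fixture."""
    dataset, _ = dta35_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MotoneuronPool(dataset).fit()


@pytest.fixture(scope="session")
def dta35_pool(dta35_results):
    """Reconstructed-pool simulation (step 4) at N = 400."""
    return dta35_results.simulate_pool(seed=101)


def constant_rate_train(rate_hz: float, t0: float, t1: float, mn_id: int = 1,
                        threshold: float | None = None,
                        sampling_rate: float = 2048.0) -> SpikeTrain:
    times = np.arange(t0, t1, 1.0 / rate_hz)
    return SpikeTrain(mn_id=mn_id, firing_times=times,
                      recruitment_threshold=threshold, sampling_rate=sampling_rate)


@pytest.fixture()
def const_train(short_protocol):
    return constant_rate_train(8.0, 1.0, 9.0)


def constant_current(amps: float, duration: float = 10.0, fs: float = 2048.0) -> DriveSignal:
    t = np.arange(0.0, duration, 1.0 / fs)
    return DriveSignal(t, np.full(t.size, amps), role="current")
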