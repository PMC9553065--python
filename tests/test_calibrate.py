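"""Inert-period extraction, size calibration and pool-distribution fitting."""

import numpy as np
import pytest

from monpool import lif
from monpool.calibrate import (IpDistribution, SizeDistribution,
                               calibrate_cmd, calibrate_size,
                               detect_saturation, fit_derecruitment,
                               fit_ip_distribution, fit_size_distribution)
from monpool.drive import CurrentInput
from monpool.spiketrain import (ContractionProtocol, DriveSignal, RateSeries,
                                SpikeTrain, filtered_idf,
                                instantaneous_discharge_frequency)


def _trend(protocol, fn):
    grid = protocol.time_grid()
    vals = fn(grid)
    return RateSeries(grid, vals, kind="trend")


def _ramp_current(protocol, i0, i1):
    t = protocol.time_grid()
    _, t1, t2, t3, t4, _ = protocol.t_tr
    vals = np.interp(t, [t[0], t1, t2, t3, t4, t[-1]], [0, 0, 1, 1, 0, 0])
    sig = DriveSignal(t, i0 + (i1 - i0) * vals, role="current")
    return CurrentInput(signal=sig, gain=1.0, onset_time=t1, anchors=(i0, i1))


class TestDetectSaturation:
    def test_constant_trend_saturates(self, short_protocol):
        trend = _trend(short_protocol, lambda t: np.full(t.size, 12.0))
        saturating, ip = detect_saturation(trend, short_protocol)
        assert saturating and ip == pytest.approx(1 / 12.0)

    def test_linear_ramp_to_plateau_does_not_saturate(self, short_protocol):
        t1, t2 = short_protocol.t_tr[1], short_protocol.t_tr[2]

        def fn(t):
            ramp = np.clip((t - t1) / (t2 - t1), 0, 1)
            return 10.0 * ramp

        saturating, ip = detect_saturation(_trend(short_protocol, fn), short_protocol)
        assert not saturating and ip is None

    def test_mid_ramp_saturation_reciprocal_ip(self, short_protocol):
        t1, t2 = short_protocol.t_tr[1], short_protocol.t_tr[2]
        mid = (t1 + t2) / 2.0

        def fn(t):
            return np.where(t < mid, 25.0 * np.clip((t - t1) / (mid - t1), 0, 1), 25.0)

        saturating, ip = detect_saturation(_trend(short_protocol, fn), short_protocol)
        assert saturating and ip == pytest.approx(0.04)

    def test_empty_plateau_rejected(self, short_protocol):
        trend = _trend(short_protocol, lambda t: np.zeros(t.size))
        with pytest.raises(ValueError, match="plateau"):
            detect_saturation(trend, short_protocol)


class TestIpDistribution:
    def test_published_fit_implies_25_hz_max_rate(self):
        dist = IpDistribution(a=0.04, b=0.05)
        assert dist.max_rate_first_mn == pytest.approx(25.0)

    def test_generate_then_fit_four_significant_figures(self):
        truth = IpDistribution(a=0.03, b=0.2)
        pairs = [(j, float(truth(j))) for j in (10, 40, 90, 160, 250, 380)]
        fit = fit_ip_distribution(pairs)
        assert fit.a == pytest.approx(0.03, rel=1e-4)
        assert fit.b == pytest.approx(0.2, rel=1e-4)

    def test_noisy_biased_subsample_within_ten_percent(self):
        rng = np.random.default_rng(5)
        truth = IpDistribution(a=0.04, b=0.06)
        # high-threshold-biased draw (weights ∝ (j/N)²) with 2% measurement noise
        j_all = np.arange(1, 401)
        w = (j_all / 400.0) ** 2
        js = np.sort(rng.choice(j_all, size=20, replace=False, p=w / w.sum()))
        pairs = [(int(j), float(truth(j)) * (1 + rng.normal(0, 0.02))) for j in js]
        fit = fit_ip_distribution(pairs)
        assert fit.a == pytest.approx(0.04, rel=0.10)
        assert abs(fit.b - 0.06) < 0.03

    def test_single_pair_instructs_anchors(self):
        with pytest.raises(ValueError, match="anchor"):
            fit_ip_distribution([(100, 0.05)])


class TestSizeDistribution:
    def test_published_coefficients_give_max_area(self):
        dist = SizeDistribution(s_min=1.49e-7, delta_s=2.4, c=1.47, n_pool=400)
        assert dist(400) * 1e6 == pytest.approx(0.36, abs=0.005)

    def test_generate_then_fit_four_significant_figures(self):
        truth = SizeDistribution(s_min=1.6e-7, delta_s=2.4, c=1.3, n_pool=400)
        pairs = [(j, float(truth(j))) for j in (20, 60, 120, 200, 300, 390)]
        fit = fit_size_distribution(pairs, delta_s=2.4, n_pool=400)
        assert fit.s_min == pytest.approx(1.6e-7, rel=1e-4)
        assert fit.c == pytest.approx(1.3, rel=1e-4)

    def test_noisy_biased_subsample_within_ten_percent(self):
        rng = np.random.default_rng(11)
        truth = SizeDistribution(s_min=1.49e-7, delta_s=2.4, c=1.47, n_pool=400)
        j_all = np.arange(1, 401)
        w = (j_all / 400.0) ** 2
        js = np.sort(rng.choice(j_all, size=20, replace=False, p=w / w.sum()))
        pairs = [(int(j), float(truth(j)) * (1 + rng.normal(0, 0.02))) for j in js]
        fit = fit_size_distribution(pairs, delta_s=2.4, n_pool=400)
        assert fit.s_min == pytest.approx(1.49e-7, rel=0.10)
        assert fit.c == pytest.approx(1.47, rel=0.10)

    def test_monotone_even_from_unordered_pairs(self):
        pairs = [(50, 2.0e-7), (150, 1.8e-7), (300, 2.6e-7)]
        fit = fit_size_distribution(pairs)
        j = np.arange(1, 401)
        assert np.all(np.diff(fit(j)) > 0)


class TestCalibrateSize:
    def test_known_size_recovered_within_two_percent(self, short_protocol):
        s_true = 2.5e-7
        ip = 0.04
        p = lif.params_from_size(s_true, ip=ip)
        current = _ramp_current(short_protocol, 0.2 * p.rheobase, 2.5 * p.rheobase)
        train = lif.simulate(p, current.signal, dt=1e-4)
        grid_train = SpikeTrain(mn_id=1, firing_times=train.firing_times,
                                sampling_rate=short_protocol.sampling_rate)
        target = filtered_idf(instantaneous_discharge_frequency(grid_train, short_protocol))
        s_hat, j_hat, metrics = calibrate_size(target, ip, current, short_protocol,
                                               target_train=grid_train)
        assert s_hat == pytest.approx(s_true, rel=0.02)
        assert metrics.r2 > 0.95

    def test_recovered_size_is_local_minimum(self, short_protocol):
        s_true = 2.0e-7
        ip = 0.04
        p = lif.params_from_size(s_true, ip=ip)
        current = _ramp_current(short_protocol, 0.2 * p.rheobase, 2.5 * p.rheobase)
        train = lif.simulate(p, current.signal, dt=1e-4)
        grid_train = SpikeTrain(mn_id=1, firing_times=train.firing_times,
                                sampling_rate=short_protocol.sampling_rate)
        target = filtered_idf(instantaneous_discharge_frequency(grid_train, short_protocol))

        def j_at(s):
            t0, _, t2, t3, _, _ = short_protocol.t_tr
            win = (target.times >= t0) & (target.times <= (t2 + t3) / 2)
            sim = lif.simulate(lif.params_from_size(s, ip=ip), current.signal,
                               dt=1e-4, t_stop=t3)
            gt = SpikeTrain(mn_id=0, firing_times=sim.firing_times,
                            sampling_rate=short_protocol.sampling_rate)
            fidf = filtered_idf(instantaneous_discharge_frequency(gt, short_protocol))
            return float(np.sqrt(np.mean((fidf.values[win] - target.values[win]) ** 2)))

        s_hat, j_hat, _ = calibrate_size(target, ip, current, short_protocol)
        assert j_hat <= j_at(s_hat * 1.1) + 1e-9
        assert j_hat <= j_at(s_hat * 0.9) + 1e-9

    def test_unreachable_unit_raises(self, short_protocol):
        # current never exceeds the rheobase of even the smallest admissible size
        i_max = 0.5 * lif.params_from_size(1.0e-7).rheobase
        current = _ramp_current(short_protocol, 0.1 * i_max, i_max)
        grid = short_protocol.time_grid()
        target = RateSeries(grid, np.zeros(grid.size), kind="FIDF")
        with pytest.raises(ValueError, match="no spikes"):
            calibrate_size(target, 0.04, current, short_protocol)


class TestDerecruitment:
    @staticmethod
    def _trains_with_ratio(protocol, i0, i1, ratio):
        """Trains whose first/last discharges sit at currents (i_rec, ratio·i_rec)."""
        _, t1, t2, t3, t4, _ = protocol.t_tr
        trains = []
        for k, i_rec in enumerate(np.linspace(8e-9, 25e-9, 10)):
            t_on = t1 + (i_rec - i0) / (i1 - i0) * (t2 - t1)
            t_off = t3 + (i1 - ratio * i_rec) / (i1 - i0) * (t4 - t3)
            times = np.concatenate([np.arange(t_on, t_off - 0.04, 0.08), [t_off]])
            trains.append(SpikeTrain(mn_id=k + 1, firing_times=times))
        return trains

    def test_known_ratio_recovered(self, short_protocol):
        i0, i1 = 2e-9, 30e-9
        current = _ramp_current(short_protocol, i0, i1)
        trains = self._trains_with_ratio(short_protocol, i0, i1, 0.9)
        k_hat = fit_derecruitment(trains, current, short_protocol)
        assert k_hat == pytest.approx(0.9, rel=0.02)

    def test_identical_thresholds_give_unity_with_warning(self, short_protocol):
        i0, i1 = 2e-9, 30e-9
        current = _ramp_current(short_protocol, i0, i1)
        trains = self._trains_with_ratio(short_protocol, i0, i1, 1.0)
        with pytest.warns(UserWarning, match="clipped"):
            k_hat = fit_derecruitment(trains, current, short_protocol)
        assert k_hat == pytest.approx(1.0, abs=0.01)


class TestCalibrateCmd:
    @pytest.fixture(scope="class")
    def cmd_setup(self, short_protocol):
        """Derecruitment trains generated with known C_m^d = 2.0 uF/cm²."""
        protocol = short_protocol
        kth = 0.9
        cmd_true = 2.0e-2
        sizes = [1.8e-7, 2.3e-7, 2.8e-7]
        ips = [0.045, 0.05, 0.055]
        p_hi = lif.params_from_size(max(sizes), ip=0.05)
        current = _ramp_current(protocol, 0.2 * p_hi.rheobase, 2.0 * p_hi.rheobase)
        targets = []
        for s, ip in zip(sizes, ips):
            der = lif.DerecruitmentParams(kth_ratio=kth, cmd=cmd_true,
                                          switch_time=protocol.t_tr[3])
            tr = lif.simulate(lif.params_from_size(s, ip=ip), current.signal,
                              dt=1e-4, derecruit=der)
            gt = SpikeTrain(mn_id=0, firing_times=tr.firing_times,
                            sampling_rate=protocol.sampling_rate)
            targets.append(filtered_idf(instantaneous_discharge_frequency(gt, protocol)))
        return sizes, ips, targets, current, kth, cmd_true

    def test_known_cmd_recovered_within_one_grid_step(self, short_protocol, cmd_setup):
        sizes, ips, targets, current, kth, cmd_true = cmd_setup
        cmd_hat = calibrate_cmd(sizes, ips, targets, current, short_protocol, kth)
        assert abs(cmd_hat - cmd_true) <= 0.1e-2 + 1e-9

    def test_baseline_cmd_recovered_at_lower_boundary(self, short_protocol):
        kth = 0.9
        sizes = [2.0e-7, 2.5e-7]
        ips = [0.045, 0.05]
        p_hi = lif.params_from_size(max(sizes), ip=0.05)
        current = _ramp_current(short_protocol, 0.2 * p_hi.rheobase, 2.0 * p_hi.rheobase)
        targets = []
        for s, ip in zip(sizes, ips):
            der = lif.DerecruitmentParams(kth_ratio=kth, cmd=lif.CM,
                                          switch_time=short_protocol.t_tr[3])
            tr = lif.simulate(lif.params_from_size(s, ip=ip), current.signal,
                              dt=1e-4, derecruit=der)
            gt = SpikeTrain(mn_id=0, firing_times=tr.firing_times,
                            sampling_rate=short_protocol.sampling_rate)
            targets.append(filtered_idf(instantaneous_discharge_frequency(gt, short_protocol)))
        with pytest.warns(UserWarning, match="boundary"):
            cmd_hat = calibrate_cmd(sizes, ips, targets, current, short_protocol, kth)
        assert cmd_hat == pytest.approx(lif.CM, abs=1e-9)
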