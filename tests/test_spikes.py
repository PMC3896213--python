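"""LIF array: closed-form checks, antidromic resetting, refractoriness."""

import math

import numpy as np
import pytest

from touchdome.spikes import (
    LIFParameters,
    SpikeTrain,
    baseline_subthreshold_check,
    constant_drive_isi,
    integrate_afferent,
    read_spike_train,
    write_spike_train,
)
from touchdome.transduction import CurrentTrace, TransductionParameters


def const_current(i_mA, n=4000, dt=1.0):
    t = np.arange(n) * dt
    return CurrentTrace(t, np.full(n, i_mA), 1)


def merged_rate_oracle(currents_mA, params):
    """Event-based closed form for constant drives with mutual resetting.

    All zones reset together, so every cycle restarts from the reset
    potential and the first zone to reach threshold (the strongest drive)
    sets the period: ISI = refractory + tau ln(RI/(RI - vbar)).
    """
    isis = [constant_drive_isi(i, params) for i in currents_mA]
    best = min(isis)
    return 0.0 if math.isinf(best) else 1000.0 / best


class TestSingleZone:
    def test_subthreshold_drive_is_silent(self):
        params = LIFParameters()
        i = 0.9 * params.threshold_mV / params.resistance_ohm
        train = integrate_afferent([const_current(i)], params)
        assert len(train) == 0

    @pytest.mark.parametrize("ri_mv", [35.0, 60.0, 90.0])
    def test_isi_matches_closed_form(self, ri_mv):
        # RK4 with fine substeps: ISI within one integration step (and 2%)
        # of refractory + tau ln(RI/(RI - vbar))
        params = LIFParameters(substeps=20)
        i = ri_mv / params.resistance_ohm
        train = integrate_afferent([const_current(i)], params)
        isis = np.diff(train.times_ms)
        expected = constant_drive_isi(i, params)
        assert np.allclose(isis, expected, rtol=0.02)
        assert abs(isis.mean() - expected) <= 1.0 / params.substeps + 1e-9

    def test_default_grid_isi_within_one_sample(self):
        params = LIFParameters()  # 1-ms steps, spike times on the grid
        i = 60.0 / params.resistance_ohm
        train = integrate_afferent([const_current(i)], params)
        expected = constant_drive_isi(i, params)
        assert abs(np.diff(train.times_ms).mean() - expected) <= 1.0

    def test_threshold_drive_boundary(self):
        params = LIFParameters()
        exactly = params.threshold_mV / params.resistance_ohm
        assert constant_drive_isi(exactly, params) == math.inf


class TestArrayResetting:
    def test_driver_dominates_merged_rate(self):
        # merged rate under two constant suprathreshold drives equals the
        # stronger zone's solo rate (antidromic resetting suppresses the
        # weaker zone)
        params = LIFParameters(substeps=10)
        r = params.resistance_ohm
        hi, lo = 70.0 / r, 40.0 / r
        both = integrate_afferent([const_current(hi), const_current(lo)], params)
        solo = integrate_afferent([const_current(hi)], params)
        assert len(both) == len(solo)
        np.testing.assert_allclose(both.times_ms, solo.times_ms)
        rate = 1000.0 * len(both) / both.duration_ms
        assert rate == pytest.approx(merged_rate_oracle([hi, lo], params), rel=0.05)

    def test_all_spikes_from_strongest_zone(self):
        params = LIFParameters(substeps=10)
        r = params.resistance_ohm
        train = integrate_afferent(
            [const_current(40.0 / r), const_current(70.0 / r)], params
        )
        # steady state: the faster zone (index 1) wins every cycle
        assert np.all(train.zones[1:] == 1)

    def test_adding_weaker_zone_never_raises_rate(self):
        params = LIFParameters(substeps=10)
        r = params.resistance_ohm
        strong = const_current(65.0 / r)
        solo = integrate_afferent([strong], params)
        for weak_mv in (10.0, 35.0, 64.0):
            both = integrate_afferent([strong, const_current(weak_mv / r)], params)
            assert len(both) <= len(solo) + 1

    def test_equal_drives_tie_break_lowest_zone(self):
        params = LIFParameters()
        r = params.resistance_ohm
        c = const_current(70.0 / r)
        train = integrate_afferent([c, c, c], params)
        assert np.all(train.zones == 0)

    def test_refractory_spacing_always_respected(self):
        params = LIFParameters()
        rng = np.random.default_rng(11)
        t = np.arange(3000) * 1.0
        currents = [
            CurrentTrace(t, 1.3e-7 * rng.random(3000), 1) for _ in range(4)
        ]
        train = integrate_afferent(currents, params)
        assert len(train) > 10
        assert np.all(np.diff(train.times_ms) >= params.refractory_ms - 1e-9)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            integrate_afferent(
                [const_current(1e-7, n=100), const_current(1e-7, n=90)],
                LIFParameters(),
            )

    def test_empty_zone_list_rejected(self):
        with pytest.raises(ValueError):
            integrate_afferent([], LIFParameters())


class TestBaselineCheck:
    def test_printed_offset_is_subthreshold(self):
        # R*beta = (5 ms / 1e-8 mF) * 5.643e-8 mA = 28.2 mV < 30 mV
        report = baseline_subthreshold_check(
            LIFParameters(), TransductionParameters(5.643e-8, 0, 0)
        )
        assert report["passes"]
        assert report["offset_drive_mV"] == pytest.approx(28.215, abs=0.01)

    def test_zero_offset_margin_is_threshold(self):
        report = baseline_subthreshold_check(
            LIFParameters(), TransductionParameters(0.0, 0, 0)
        )
        assert report["margin_mV"] == 30.0

    def test_large_offset_fails(self):
        report = baseline_subthreshold_check(
            LIFParameters(), TransductionParameters(1e-7, 0, 0)
        )
        assert not report["passes"]
        assert report["offset_drive_mV"] == pytest.approx(50.0)


class TestSpikeTrainIO:
    def test_round_trip(self, tmp_path):
        train = SpikeTrain(np.array([3.0, 8.0, 15.0]), np.array([0, 1, 0]), 2)
        path = tmp_path / "train.csv"
        write_spike_train(train, path)
        back = read_spike_train(path, refractory_ms=1.0)
        np.testing.assert_array_equal(back.times_ms, train.times_ms)
        np.testing.assert_array_equal(back.zones, train.zones)

    def test_refractory_violation_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_ms,zone\n1.0,0\n1.5,0\n")
        with pytest.raises(ValueError, match="refractory"):
            read_spike_train(path, refractory_ms=1.0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([5.0, 2.0]), np.array([0, 0]), 1)
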