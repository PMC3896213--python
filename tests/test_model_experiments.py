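"""End-to-end pipeline: simulation determinism, driver-effect signs, surveys.

These tests run the full displacement -> SED -> current -> spike pipeline
on a reduced protocol (three depths, one acceleration, two repetitions,
2.5-s hold) with noise disabled where determinism matters; the parameter
sets are chosen so the primary cluster fires deterministically at the
deeper displacements.
"""

import numpy as np
import pandas as pd
import pytest

from touchdome.arbor import ArborConfiguration
from touchdome.experiments import (
    PROTOTYPICAL_ARBORS,
    TABLE_GROUPING_PAIRS,
    compare_architectures,
    per_unit_gains,
    run_fillup_survey,
    run_grouping_experiment,
    simulate_pair,
    suprathreshold_percent_change,
)
from touchdome.model import AfferentModel
from touchdome.protocol import StimulusProtocol
from touchdome.transduction import NoiseConfig, TransductionParameters

FAST_PROTOCOL = StimulusProtocol(
    depths_mm=(0.12, 0.24, 0.36),
    accelerations_mm_s2=(81.0,),
    hold_s=2.5,
    repetitions=2,
)
# suprathreshold at the deeper displacements without noise
FIRING_PARAMS = TransductionParameters(5.45e-8, 2e-13, 4e-11)
QUIET_PARAMS = TransductionParameters(5.0e-8, 1e-15, 1e-13)


def fast_model(clusters=(8, 5, 3, 1), noise=False):
    return AfferentModel(
        ArborConfiguration(clusters),
        protocol=FAST_PROTOCOL,
        noise=NoiseConfig(enabled=bool(noise)),
    )


class TestSimulate:
    def test_subthreshold_offset_never_fires(self):
        sim = fast_model().simulate(QUIET_PARAMS, seed=0)
        assert sim.rates["n_spikes"].sum() == 0
        assert np.all(sim.hfr == 0.0) and np.all(sim.rfr == 0.0)

    def test_same_seed_is_bit_identical(self):
        model = fast_model(noise=True)
        a = model.simulate(FIRING_PARAMS, seed=7)
        b = model.simulate(FIRING_PARAMS, seed=7)
        pd.testing.assert_frame_equal(a.rates, b.rates)

    def test_noise_off_rates_monotone_in_depth(self):
        sim = fast_model().simulate(FIRING_PARAMS, seed=0)
        by_depth = sim.rates.groupby("depth_mm")[["hfr_hz", "rfr_hz"]].mean()
        assert by_depth["hfr_hz"].is_monotonic_increasing
        assert by_depth["rfr_hz"].is_monotonic_increasing

    def test_ramp_rate_monotone_in_acceleration(self):
        protocol = StimulusProtocol(
            depths_mm=(0.36,), accelerations_mm_s2=(20.0, 81.0, 1143.0),
            hold_s=2.5, repetitions=1,
        )
        model = AfferentModel(
            ArborConfiguration((8, 5, 3, 1)), protocol=protocol,
            noise=NoiseConfig(enabled=False),
        )
        sim = model.simulate(FIRING_PARAMS, seed=0)
        rates = sim.rates.sort_values("acceleration_mm_s2")["rfr_hz"]
        assert rates.is_monotonic_increasing

    def test_latency_non_increasing_with_acceleration(self):
        protocol = StimulusProtocol(
            depths_mm=(0.36,), accelerations_mm_s2=(20.0, 81.0, 1143.0),
            hold_s=2.5, repetitions=1,
        )
        model = AfferentModel(
            ArborConfiguration((8, 5, 3, 1)), protocol=protocol,
            noise=NoiseConfig(enabled=False),
        )
        sim = model.simulate(FIRING_PARAMS, seed=0, keep_trains=True)
        lat = sim.rates.sort_values("acceleration_mm_s2")["latency_ms"].to_numpy()
        assert np.all(np.diff(lat) <= 0)

    def test_spike_trains_respect_refractory(self):
        model = fast_model(noise=True)
        sim = model.simulate(FIRING_PARAMS, seed=3, keep_trains=True)
        for train in sim.trains:
            if len(train) > 1:
                assert np.all(np.diff(train.times_ms) >= 1.0 - 1e-9)


class TestStructuralSigns:
    def test_bigger_primary_cluster_fires_more(self):
        # the driver-effect prediction: concentrating units in the primary
        # cluster raises suprathreshold firing
        model = fast_model()
        sim_base = model.simulate(FIRING_PARAMS, seed=0)
        sim_ref, sim_skew = simulate_pair(
            model, ArborConfiguration((10, 5, 1, 1)), FIRING_PARAMS, seed=0
        )
        change = suprathreshold_percent_change(sim_ref, sim_base)
        assert change == pytest.approx(0.0)  # identical configuration
        assert suprathreshold_percent_change(sim_skew, sim_base) >= 0.0

    def test_identity_perturbation_is_zero(self):
        model = fast_model(noise=True)
        pairs = ({"arbor": 1, "which": "primary", "before": (8, 5, 3, 1),
                  "after": (8, 5, 3, 1), "delta": 1},)
        table = run_grouping_experiment(model, {1: FIRING_PARAMS}, pairs, seed=0)
        assert table["pct_change"].iloc[0] == pytest.approx(0.0)

    def test_unit_total_mismatch_rejected(self):
        model = fast_model()
        pairs = ({"arbor": 1, "which": "primary", "before": (8, 5, 3, 1),
                  "after": (9, 5, 3, 1), "delta": 1},)
        with pytest.raises(ValueError, match="conserved"):
            run_grouping_experiment(model, {1: FIRING_PARAMS}, pairs, seed=0)

    def test_table_pairs_conserve_units(self):
        for pair in TABLE_GROUPING_PAIRS:
            before = ArborConfiguration(pair["before"])
            after = ArborConfiguration(pair["after"])
            assert before.total_units == after.total_units
            assert before.total_units == PROTOTYPICAL_ARBORS[pair["arbor"]].total_units

    def test_fillup_survey_shape_and_zero_baseline(self):
        model = fast_model(noise=True)
        table = run_fillup_survey(model, FIRING_PARAMS, max_added=2, seed=0)
        assert set(table["strategy"]) == {"secondary", "smallest"}
        zero = table[table["units_added"] == 0]
        assert np.all(zero["pct_change"] == 0.0)
        assert table["total_units"].max() == 19

    def test_architecture_comparison_outputs(self):
        model = fast_model(noise=True)
        cmp_ = compare_architectures(
            model, ArborConfiguration((10, 1, 1)),
            ArborConfiguration((4, 4, 4, 4, 4)), FIRING_PARAMS, seed=0,
        )
        assert set(cmp_.fits) == {"a", "b"}
        assert len(cmp_.table) == 2 * FAST_PROTOCOL.n_total
        assert 0.0 <= cmp_.p_kappa <= 1.0

    def test_per_unit_gains_aggregation(self):
        table = pd.DataFrame(
            {"which": ["primary", "primary", "secondary"],
             "pct_per_unit": [8.0, 6.0, 3.0]}
        )
        gains = per_unit_gains(table)
        assert gains["primary"] == pytest.approx(7.0)
        assert gains["secondary"] == pytest.approx(3.0)


class TestFitPlumbing:
    def test_model_without_target_cannot_fit(self):
        with pytest.raises(ValueError, match="target"):
            fast_model().fit()

    def test_summary_mentions_parameters_and_score(self):
        model = AfferentModel.from_regressions(
            ArborConfiguration((6, 4, 3)), protocol=FAST_PROTOCOL,
        )
        res = model.fit(
            seed=0, n_domain=8, n_design=6, max_iterations=2, n_starts=1,
        )
        text = res.summary()
        assert "beta" in text and "combined fss" in text
        assert "{6,4,3}" in text

    def test_sed_traces_cached_per_stimulus(self):
        model = fast_model()
        a = model.sed(0.12, 81.0)
        assert model.sed(0.12, 81.0) is a
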