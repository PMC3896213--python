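"""Skin-mechanics stage: ramp kinematics, surrogate SED, QLV convolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from touchdome.mechanics import (
    DisplacementStimulus,
    MechanicsError,
    SEDFormatError,
    SEDTrace,
    SkinParameters,
    instantaneous_sed,
    make_ramp_hold,
    qlv_convolve,
    read_sed_trace,
    sed_trace,
    write_sed_trace,
)


class TestRampHold:
    @pytest.mark.parametrize(
        "depth,accel,expected_tramp",
        [
            (0.36, 1143.0, math.sqrt(2 * 0.36 / 1143)),  # ~25.1 ms
            (0.2, 20.0, math.sqrt(2 * 0.2 / 20)),  # ~141.4 ms
            (0.04, 81.0, math.sqrt(2 * 0.04 / 81)),
        ],
    )
    def test_ramp_duration_closed_form(self, depth, accel, expected_tramp):
        stim = make_ramp_hold(depth, accel, 5.0)
        assert stim.ramp_duration_s == pytest.approx(expected_tramp, rel=1e-12)

    def test_trajectory_shape_and_final_depth(self):
        stim = make_ramp_hold(0.36, 1143.0, 5.0)
        t_ms, d = stim.trajectory()
        assert d[0] == 0.0
        assert d[-1] == 0.36
        assert np.all(np.diff(d) >= 0)
        # quadratic during the ramp: d(10 ms) = a t^2 / 2
        i = 10
        assert d[i] == pytest.approx(0.5 * 1143.0 * (0.010) ** 2, rel=1e-9)
        assert len(t_ms) == pytest.approx(stim.duration_s * 1000 + 1, abs=1)

    def test_zero_depth_trajectory_is_flat(self):
        stim = make_ramp_hold(0.0, 100.0, 1.0)
        assert stim.ramp_duration_s == 0.0
        _, d = stim.trajectory()
        assert np.all(d == 0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(depth_mm=-0.1, ramp_acceleration_mm_s2=10, hold_s=5),
            dict(depth_mm=0.6, ramp_acceleration_mm_s2=10, hold_s=5),
            dict(depth_mm=0.1, ramp_acceleration_mm_s2=0, hold_s=5),
            dict(depth_mm=0.1, ramp_acceleration_mm_s2=10, hold_s=0),
        ],
    )
    def test_invalid_stimuli_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DisplacementStimulus(**kwargs)


class TestInstantaneousSED:
    def test_undeformed_skin_has_zero_sed(self):
        assert instantaneous_sed(0.0, SkinParameters()) == 0.0

    def test_small_strain_effective_modulus(self):
        # W ~ 3 (C10 + C01) e^2, so the uniaxial modulus W''(0) must equal
        # 6 (C10 + C01) = 337,542 Pa; checked by finite differences on a
        # tissue column over an effectively rigid substrate
        p = SkinParameters(substrate_modulus_pa=1e16)
        h_t_mm = p.tissue_thickness_um / 1000.0
        e = 1e-3
        w = instantaneous_sed(e * h_t_mm, p)
        modulus = 2.0 * w / e**2
        assert modulus == pytest.approx(6 * (p.c10_pa + p.c01_pa), rel=5e-3)

    def test_rigid_substrate_takes_no_displacement(self):
        p = SkinParameters(substrate_modulus_pa=1e16)
        soft = SkinParameters()
        # with a rigid substrate all displacement deforms the tissue, so
        # SED must exceed the compliant-substrate value at the same depth
        assert instantaneous_sed(0.2, p) > instantaneous_sed(0.2, soft)

    def test_strictly_increasing_in_depth(self):
        p = SkinParameters()
        depths = np.linspace(0.0, 0.36, 19)
        w = [instantaneous_sed(d, p) for d in depths]
        assert np.all(np.diff(w) > 0)

    def test_negative_depth_rejected(self):
        with pytest.raises(MechanicsError):
            instantaneous_sed(-0.01, SkinParameters())


class TestQLV:
    def test_step_input_relaxes_to_g_inf(self):
        # G(0) = 1 and G(inf) = 1 - g1 - g2 = 0.383 with printed Prony pairs
        p = SkinParameters()
        t = np.arange(120_001, dtype=float)  # 120 s at 1 kHz
        w = np.where(t > 0, 100.0, 0.0)
        out = qlv_convolve(t, w, p)
        assert out.sed_pa[1] == pytest.approx(100.0, rel=2e-3)
        assert out.sed_pa[-1] == pytest.approx(0.383 * 100.0, rel=1e-2)

    def test_elastic_limit_is_identity(self):
        p = SkinParameters(prony_g1=0.0, prony_g2=0.0)
        t = np.arange(2001, dtype=float)
        w = np.linspace(0, 500.0, t.size)
        out = qlv_convolve(t, w, p)
        np.testing.assert_allclose(out.sed_pa, w, rtol=1e-12)

    def test_recursive_update_matches_direct_quadrature(self):
        # independent oracle: trapezoidal evaluation of the hereditary
        # integral eps(t) = sum G(t - s_k) dW_k
        p = SkinParameters()
        stim = make_ramp_hold(0.2, 81.0, 5.0)
        t_ms, d = stim.trajectory()
        w = np.array([instantaneous_sed(x, p) for x in d])
        fast = qlv_convolve(t_ms, w, p).sed_pa

        tau1, tau2 = p.prony_tau1_s * 1000, p.prony_tau2_s * 1000
        g = lambda t: p.g_inf + p.prony_g1 * np.exp(-t / tau1) + p.prony_g2 * np.exp(-t / tau2)
        dw = np.diff(w)
        mid = 0.5 * (t_ms[1:] + t_ms[:-1])
        direct = np.array(
            [w[0]] + [float(np.sum(g(t_ms[n] - mid[:n]) * dw[:n])) for n in range(1, len(t_ms))]
        )
        scale = np.max(np.abs(direct))
        np.testing.assert_allclose(fast, direct, atol=1e-3 * scale)

    def test_grid_refinement_convergence(self):
        p = SkinParameters()
        results = {}
        for fs in (1000.0, 4000.0):
            stim = make_ramp_hold(0.2, 81.0, 2.0, sampling_rate_hz=fs)
            t_ms, d = stim.trajectory()
            w = np.array([instantaneous_sed(x, p) for x in d])
            results[fs] = qlv_convolve(t_ms, w, p).sed_pa[-1]
        assert results[1000.0] == pytest.approx(results[4000.0], rel=1e-3)

    def test_hold_phase_relaxation_bounds(self):
        p = SkinParameters()
        trace = sed_trace(make_ramp_hold(0.28, 81.0, 5.0), p)
        stim = trace.stimulus
        hold = trace.sed_pa[int(stim.ramp_duration_s * 1000) + 2 :]
        assert np.all(np.diff(hold) <= 1e-9)  # non-increasing during hold
        floor = p.g_inf * instantaneous_sed(0.28, p)
        assert np.all(hold >= floor - 1e-9)

    @settings(max_examples=20, deadline=None)
    @given(depth=st.floats(0.02, 0.36), accel=st.sampled_from([20.0, 81.0, 1143.0]))
    def test_peak_and_plateau_monotone_in_depth(self, depth, accel):
        p = SkinParameters()
        lo = sed_trace(make_ramp_hold(depth / 2, accel, 3.0), p)
        hi = sed_trace(make_ramp_hold(depth, accel, 3.0), p)
        assert hi.sed_pa.max() >= lo.sed_pa.max()
        assert hi.sed_pa[-1] >= lo.sed_pa[-1]


class TestSEDTraceIO:
    def test_round_trip_identity(self, tmp_path):
        trace = sed_trace(make_ramp_hold(0.12, 81.0, 3.0))
        path = tmp_path / "trace.csv"
        write_sed_trace(trace, path)
        back = read_sed_trace(path)
        np.testing.assert_allclose(back.time_ms, trace.time_ms)
        np.testing.assert_allclose(back.sed_pa, trace.sed_pa, rtol=1e-12)

    def test_negative_sed_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_ms,sed_pa\n0,1.0\n1,-2.0\n2,1.0\n")
        with pytest.raises(SEDFormatError, match="sample 1"):
            read_sed_trace(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("time_ms,value\n0,1\n1,2\n")
        with pytest.raises(SEDFormatError, match="sed_pa"):
            read_sed_trace(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SEDFormatError):
            read_sed_trace(path)

    def test_non_uniform_grid_rejected(self, tmp_path):
        path = tmp_path / "grid.csv"
        path.write_text("time_ms,sed_pa\n0,1\n1,2\n3,2\n")
        with pytest.raises(SEDFormatError, match="uniform"):
            read_sed_trace(path)
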