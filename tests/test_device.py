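"""Conductance-update model: curve identities, pulses, profiles, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memsnn import (
    DeviceParams,
    Direction,
    SynapseArray,
    apply_pulse,
    delta_w_profile,
    fit_nonlinearity,
    ltd_curve,
    ltp_curve,
    ratio_profile,
)
from memsnn.device import _ltd_index, _ltp_index, ratio_saturation_band
from memsnn.errors import FittingError, RangeError

NU_SET = [-10.0, -5.0, -1.0, 1.0, 5.0, 10.0]


class TestCurves:
    @pytest.mark.parametrize("nu", NU_SET + [0.0, 1e-9])
    def test_boundary_identities_exact(self, nu):
        """LTP starts at g_min; the LTD branch spans [g_min, g_max] exactly."""
        p = DeviceParams(nu_ltp=nu, nu_ltd=nu)
        assert ltp_curve(0, p) == p.g_min
        assert ltd_curve(p.resolution, p) == p.g_max
        assert ltd_curve(0, p) == p.g_min

    def test_ltp_reaches_gmax_when_exponent_equals_nu(self):
        # beta*p/resolution = 1 makes the LTP exponent -nu, i.e. full range
        p = DeviceParams(nu_ltp=10.0, nu_ltd=10.0, beta=4.0)
        assert ltp_curve(64, p) == pytest.approx(1.0, abs=1e-12)

    def test_linear_limit_values(self):
        p = DeviceParams(nu_ltp=1e-9, nu_ltd=1e-9, beta=4.0)
        assert ltp_curve(32, p) == pytest.approx(0.5, abs=1e-9)  # beta*p/256
        assert ltd_curve(128, p) == pytest.approx(0.5, abs=1e-9)  # p/256

    @pytest.mark.parametrize("nu", [1e-6, 5e-7, -1e-6])
    def test_linear_limit_matches_ramp(self, nu):
        """Near nu=0 both branches agree with the closed-form ramp to 1e-6."""
        p = DeviceParams(nu_ltp=nu, nu_ltd=nu, beta=4.0)
        ps = np.linspace(0, 256, 64)
        ramp_ltd = ps / 256.0
        ramp_ltp = np.minimum(4.0 * ps / 256.0, 1.0)
        assert np.allclose(ltd_curve(ps, p), ramp_ltd, atol=1e-6)
        assert np.allclose(ltp_curve(ps, p), ramp_ltp, atol=1e-6)

    def test_monotone_increasing_in_pulse_index(self):
        for nu in NU_SET:
            p = DeviceParams(nu_ltp=nu, nu_ltd=nu)
            ps = np.linspace(0, 256, 200)
            assert np.all(np.diff(ltp_curve(ps, p)) >= 0)
            assert np.all(np.diff(ltd_curve(ps, p)) >= 0)

    def test_pulse_index_out_of_range(self, linear_device):
        with pytest.raises(RangeError):
            ltp_curve(-1, linear_device)
        with pytest.raises(RangeError):
            ltd_curve(257, linear_device)

    @pytest.mark.parametrize("nu", NU_SET)
    def test_inversion_round_trip(self, nu):
        """curve(index(w)) == w to 1e-10 on both branches."""
        p = DeviceParams(nu_ltp=nu, nu_ltd=nu)
        w = np.linspace(0.0, 1.0, 101)
        assert np.allclose(ltp_curve(_ltp_index(w, p), p), w, atol=1e-10)
        assert np.allclose(ltd_curve(_ltd_index(w, p), p), w, atol=1e-10)


class TestApplyPulse:
    @pytest.mark.parametrize("w", [0.0, 0.1, 0.5, 0.9])
    def test_linear_ltp_step_is_beta_over_resolution(self, linear_device, w):
        assert apply_pulse(w, Direction.LTP, linear_device) == pytest.approx(
            w + 4.0 / 256.0, abs=1e-12
        )

    def test_linear_ltd_step_is_one_over_resolution(self, linear_device):
        assert apply_pulse(0.5, Direction.LTD, linear_device) == pytest.approx(
            0.5 - 1.0 / 256.0, abs=1e-12
        )

    def test_saturation_at_bounds(self, linear_device):
        assert apply_pulse(1.0, Direction.LTP, linear_device) == 1.0
        assert apply_pulse(0.0, Direction.LTD, linear_device) == 0.0

    def test_positive_nu_ltp_step_shrinks_with_weight(self):
        """Strong-then-saturating potentiation: larger step at low weight."""
        p = DeviceParams(nu_ltp=10.0, nu_ltd=10.0)
        d_low = apply_pulse(0.1, Direction.LTP, p) - 0.1
        d_high = apply_pulse(0.9, Direction.LTP, p) - 0.9
        assert d_low > d_high > 0

    def test_weight_out_of_bounds_rejected(self, linear_device):
        with pytest.raises(RangeError):
            apply_pulse(1.5, Direction.LTP, linear_device)

    @settings(deadline=None, max_examples=50)
    @given(
        nu_ltp=st.floats(-10, 10),
        nu_ltd=st.floats(-10, 10),
        w0=st.floats(0, 1),
        n_pulses=st.integers(1, 30),
        direction=st.sampled_from([Direction.LTP, Direction.LTD]),
    )
    def test_iterated_pulses_bounded_and_monotone(self, nu_ltp, nu_ltd, w0, n_pulses, direction):
        """Any pulse train keeps w in bounds and moves it monotonically."""
        p = DeviceParams(nu_ltp=nu_ltp, nu_ltd=nu_ltd)
        w = w0
        for _ in range(n_pulses):
            new = apply_pulse(w, direction, p)
            assert p.g_min <= new <= p.g_max
            if direction is Direction.LTP:
                assert new >= w
            else:
                assert new <= w
            w = new


class TestProfiles:
    def test_delta_profile_signs(self):
        for nu in [(0.0, 0.0), (10.0, -10.0), (10.0, 10.0), (-10.0, -10.0)]:
            prof = delta_w_profile(DeviceParams(*nu), 50)
            assert np.all(prof.dw_ltp >= 0)
            assert np.all(prof.dw_ltd <= 0)

    def test_linear_profile_is_flat(self, linear_device):
        prof = delta_w_profile(linear_device, 50)
        inside = prof.w <= 1.0 - 4.0 / 256.0  # beyond this one LTP pulse clips
        assert np.allclose(prof.dw_ltp[inside], 4.0 / 256.0, atol=1e-12)
        inside_ltd = prof.w >= 1.0 / 256.0
        assert np.allclose(prof.dw_ltd[inside_ltd], -1.0 / 256.0, atol=1e-12)

    def test_same_sign_pairs_move_signed_deltas_together(self):
        """For (10,10) both signed deltas fall with w; for (-10,-10) both rise."""
        up = ratio_profile(DeviceParams(10.0, 10.0), 50)
        assert up.dw_ltp.iloc[0] > up.dw_ltp.iloc[-1]
        assert up.dw_ltd.iloc[0] > up.dw_ltd.iloc[-1]
        down = ratio_profile(DeviceParams(-10.0, -10.0), 50)
        assert down.dw_ltp.iloc[0] < down.dw_ltp.iloc[-1]
        assert down.dw_ltd.iloc[0] < down.dw_ltd.iloc[-1]

    def test_linear_ratio_equals_beta(self, linear_device):
        prof = ratio_profile(linear_device, 100)
        assert np.allclose(prof.ratio, 4.0, rtol=1e-12)

    def test_symmetric_pair_ratio_constant(self):
        """(nu, -nu) devices keep a w-independent LTP/LTD magnitude ratio."""
        for nu_pair, expected in [((10.0, -10.0), 3.6313031537), ((-10.0, 10.0), 4.4145419468)]:
            prof = ratio_profile(DeviceParams(*nu_pair), 100)
            assert prof.ratio.max() / prof.ratio.min() - 1 < 1e-9
            assert prof.ratio.mean() == pytest.approx(expected, rel=1e-9)

    def test_symmetric_ratio_nu_to_zero_limit_is_beta(self):
        prof = ratio_profile(DeviceParams(1e-4, -1e-4), 100)
        assert np.allclose(prof.ratio, 4.0, rtol=1e-3)

    def test_same_sign_ratio_varies(self):
        for nu in [(10.0, 10.0), (-10.0, -10.0)]:
            prof = ratio_profile(DeviceParams(*nu), 100)
            assert prof.ratio.max() / prof.ratio.min() > 1.5

    def test_saturation_band_is_interior(self):
        for nu in [(0.0, 0.0), (10.0, -10.0), (-10.0, 10.0)]:
            lo, hi = ratio_saturation_band(DeviceParams(*nu))
            assert 0.0 < lo < hi < 1.0

    def test_degenerate_grid_rejected(self, linear_device):
        with pytest.raises(ValueError):
            ratio_profile(linear_device, 1)


class TestFitNonlinearity:
    @pytest.mark.parametrize("nu", NU_SET)
    @pytest.mark.parametrize("branch", ["ltp", "ltd"])
    def test_recovers_generating_nu(self, nu, branch):
        params = DeviceParams(nu_ltp=nu, nu_ltd=nu)
        ps = np.linspace(0, 64 if branch == "ltp" else 256, 25)
        ws = ltp_curve(ps, params) if branch == "ltp" else ltd_curve(ps, params)
        est = fit_nonlinearity(list(zip(ps, ws)), branch)
        assert est == pytest.approx(nu, rel=1e-4)

    def test_linear_data_gives_near_zero_nu(self):
        ps = np.linspace(0, 256, 20)
        ws = ps / 256.0  # LTD linear ramp
        assert abs(fit_nonlinearity(list(zip(ps, ws)), "ltd")) < 1e-3

    def test_under_determined_input_rejected(self):
        with pytest.raises(FittingError):
            fit_nonlinearity([(0, 0.0), (10, 0.2)], "ltp")

    def test_non_monotone_input_rejected(self):
        pts = [(0, 0.0), (10, 0.5), (20, 0.2), (30, 0.8)]
        with pytest.raises(FittingError):
            fit_nonlinearity(pts, "ltp")

    def test_out_of_bounds_weights_rejected(self):
        pts = [(0, 0.0), (10, 0.5), (20, 1.4)]
        with pytest.raises(RangeError):
            fit_nonlinearity(pts, "ltp")


class TestParamsAndArray:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DeviceParams(0, 0, g_min=1.0, g_max=0.0)
        with pytest.raises(ValueError):
            DeviceParams(0, 0, resolution=1)
        with pytest.raises(ValueError):
            DeviceParams(0, 0, beta=0.0)

    def test_synapse_array_bounds_enforced(self, linear_device, rng):
        with pytest.raises(RangeError):
            SynapseArray(weights=np.full((4, 4), 2.0), device=linear_device)
        arr = SynapseArray.random_uniform(5, 3, linear_device, rng)
        assert arr.weights.shape == (5, 3)
        assert arr.weights.min() >= 0.0 and arr.weights.max() <= 1.0
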