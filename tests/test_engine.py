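"""Phosphene engine: activation sampling, axon-map spatial model, and the
leaky-integrator temporal model (with independent oracles)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

import spvsim
from spvsim.errors import ConfigurationError


# ---------------------------------------------------------------------------
# Electrode activation
# ---------------------------------------------------------------------------

class TestActivation:
    def test_black_frame_all_zero(self, array10, spec_default):
        a = spvsim.electrode_activation(np.zeros((200, 200)), array10, None, spec_default)
        assert np.all(a == 0)

    def test_white_frame_one_group_gives_20_ones(self, array10, spec_default):
        sched = spvsim.checkerboard_schedule(array10, 5)
        active = sched.active_electrodes(0)
        a = spvsim.electrode_activation(np.ones((200, 200)), array10, active, spec_default)
        assert int((a == 1.0).sum()) == 20
        assert int((a == 0.0).sum()) == 80

    def test_out_of_group_amplitudes_exactly_zero(self, array10, spec_default):
        sched = spvsim.horizontal_schedule(array10, 5)
        active = sched.active_electrodes(2)
        frame = np.random.default_rng(0).random((200, 200))
        a = spvsim.electrode_activation(frame, array10, active, spec_default)
        inactive = np.setdiff1d(np.arange(100), active)
        assert np.all(a[inactive] == 0.0)

    def test_monotone_in_pixel_brightness(self, array10, spec_default):
        from spvsim.engine import electrode_pixel_indices

        frame = np.full((200, 200), 0.3)
        rc = electrode_pixel_indices(array10, spec_default, frame.shape, 60.0)
        e = 37
        frame2 = frame.copy()
        frame2[rc[e, 0], rc[e, 1]] = 0.9
        a1 = spvsim.electrode_activation(frame, array10, None, spec_default)
        a2 = spvsim.electrode_activation(frame2, array10, None, spec_default)
        assert a2[e] > a1[e]
        mask = np.arange(100) != e
        assert np.array_equal(a1[mask], a2[mask])


# ---------------------------------------------------------------------------
# Spatial model
# ---------------------------------------------------------------------------

class TestSpatialModel:
    def test_zero_activation_zero_field(self, spatial_default):
        assert np.all(spatial_default.evaluate(np.zeros(100)) == 0)

    def test_single_electrode_lambda_to_zero_is_radial_gaussian(
        self, array10, axon_map_default, spec_default
    ):
        """In the λ→0 limit only the soma survives the path maximum, so a
        single electrode's percept is the closed-form radial Gaussian."""
        rho = 300.0
        sm = spvsim.SpatialModel(
            array10, axon_map_default, spvsim.AxonMapParams(rho_um=rho, lam_um=1.0)
        )
        e = 44
        a = np.zeros(100)
        a[e] = 1.0
        field = sm.evaluate(a)
        d = np.linalg.norm(spec_default.grid_points_um() - array10.positions[e], axis=1)
        closed = np.exp(-(d**2) / (2 * rho**2)).reshape(spec_default.grid_shape)
        assert np.abs(field - closed).max() < 1e-3

    def test_two_electrode_field_between_max_and_sum(self, spatial_default):
        a1 = np.zeros(100); a1[33] = 0.8
        a2 = np.zeros(100); a2[38] = 0.6
        f1 = spatial_default.evaluate(a1)
        f2 = spatial_default.evaluate(a2)
        f12 = spatial_default.evaluate(a1 + a2)
        assert np.all(f12 >= np.maximum(f1, f2) - 1e-12)
        assert np.all(f12 <= f1 + f2 + 1e-12)

    def test_monotone_in_amplitude(self, spatial_default):
        rng = np.random.default_rng(4)
        a = rng.random(100) * 0.5
        b = a.copy()
        b[61] += 0.4
        assert np.all(spatial_default.evaluate(b) >= spatial_default.evaluate(a) - 1e-12)

    def test_single_electrode_bounded_by_one(self, spatial_default):
        a = np.zeros(100); a[50] = 1.0
        assert spatial_default.evaluate(a).max() <= 1.0 + 1e-12

    def test_elongation_along_axons(self, array10, axon_map_default):
        """Large λ stretches the percept along the local axon direction:
        the field's spatial extent grows with λ at fixed ρ."""
        a = np.zeros(100); a[4] = 1.0  # top-row electrode: long arcuate path
        lo = spvsim.SpatialModel(array10, axon_map_default, spvsim.AxonMapParams(300, 1.0)).evaluate(a)
        hi = spvsim.SpatialModel(array10, axon_map_default, spvsim.AxonMapParams(300, 1000.0)).evaluate(a)
        assert (hi > 0.1).sum() > 1.5 * (lo > 0.1).sum()

    def test_step_halving_convergence(self, array10, spec_default):
        """Halving the axon-path step (50 → 25 µm) leaves the field unchanged
        almost everywhere; a handful of foveal samples flip their
        nearest-bundle attachment, which is n_axons granularity, not path
        discretization error."""
        a = np.zeros(100); a[44] = 1.0
        coarse = spvsim.SpatialModel(
            array10, spvsim.build_axon_map(spec_default, 300, 50.0)
        ).evaluate(a)
        fine = spvsim.SpatialModel(
            array10, spvsim.build_axon_map(spec_default, 300, 25.0)
        ).evaluate(a)
        diff = np.abs(coarse - fine)
        assert np.quantile(diff, 0.99) < 0.01
        assert diff.max() < 0.15

    def test_mismatched_activation_rejected(self, spatial_default):
        with pytest.raises(ConfigurationError):
            spatial_default.evaluate(np.zeros(64))


# ---------------------------------------------------------------------------
# Temporal model
# ---------------------------------------------------------------------------

def _exact_zoh(b_I, params, dt):
    """Independent oracle: matrix-exponential propagation of the linear
    system with the input held constant over each render period."""
    A = np.array([[-params.tau_n, 0.0], [-params.alpha, -params.tau_b]])
    B = np.array([1.0, 1.0])
    Ad = expm(A * dt)
    Bd = np.linalg.solve(A, (Ad - np.eye(2)) @ B)
    x = np.zeros(2)
    out = []
    for u in b_I:
        x = Ad @ x + Bd * u
        out.append(x[1])
    return np.array(out)


class TestTemporalModel:
    def test_zero_input_zero_fixed_point(self):
        p = spvsim.TemporalParams.preset("5Hz")
        out = spvsim.integrate_temporal(np.zeros((50, 4)), p)
        assert np.all(out == 0)

    def test_presets(self):
        assert spvsim.TemporalParams.preset("5Hz") == spvsim.TemporalParams(0.2, 5.0, 0.2)
        assert spvsim.TemporalParams.preset("20Hz") == spvsim.TemporalParams(0.2, 5.0, 0.25)
        with pytest.raises(ValueError):
            spvsim.TemporalParams.preset("60Hz")

    def test_constant_input_fades_to_zero_steady_state(self):
        """With α = τ_n the algebraic steady state b* = b_I(1−α/τ_n)/τ_b is
        exactly zero: sustained stimulation fades completely."""
        p = spvsim.TemporalParams.preset("5Hz")
        b = spvsim.integrate_temporal(np.ones(60 * 90), p, 1 / 90)
        assert b.max() > 0.05  # a real transient happened
        assert abs(b[-1]) < 0.01 * b.max()

    def test_euler_tracks_exact_solution(self):
        """Forward Euler at the render period vs the matrix-exponential
        oracle on a 5-s clip-like input; the deviation stays at the ~1%
        level set by the fast brightness mode (τ_b·dt = 1/18)."""
        p = spvsim.TemporalParams.preset("5Hz")
        dt = 1 / 90
        rng = np.random.default_rng(0)
        b_I = np.convolve(rng.random(450), np.ones(23) / 23, mode="same")
        euler = spvsim.integrate_temporal(b_I, p, dt, clamp=False)
        exact = _exact_zoh(b_I, p, dt)
        assert np.abs(euler - exact).max() < 0.015 * np.abs(exact).max()

    def test_step_onset_error_at_intrinsic_euler_bound(self):
        """A full-amplitude step excites the fast mode abruptly; the Euler
        deviation then sits at the scheme's intrinsic ~1% bound."""
        p = spvsim.TemporalParams.preset("5Hz")
        dt = 1 / 90
        b_I = np.ones(450)
        err = np.abs(
            spvsim.integrate_temporal(b_I, p, dt, clamp=False) - _exact_zoh(b_I, p, dt)
        ).max()
        peak = _exact_zoh(b_I, p, dt).max()
        assert 0.009 * peak < err < 0.02 * peak

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(0.1, 3.0), st.integers(0, 2**16))
    def test_preclamp_linearity(self, scale, seed):
        """Pre-clamp the system is linear: response to a·u is a·response."""
        p = spvsim.TemporalParams.preset("5Hz")
        u = np.random.default_rng(seed).random(90)
        one = spvsim.integrate_temporal(u, p, 1 / 90, clamp=False)
        scaled = spvsim.integrate_temporal(scale * u, p, 1 / 90, clamp=False)
        assert np.allclose(scaled, scale * one, rtol=1e-9, atol=1e-12)

    def test_superposition_against_oracle(self):
        p = spvsim.TemporalParams.preset("20Hz")
        rng = np.random.default_rng(9)
        u1, u2 = rng.random(200), rng.random(200)
        lhs = spvsim.integrate_temporal(u1 + u2, p, 1 / 90, clamp=False)
        rhs = spvsim.integrate_temporal(u1, p, 1 / 90, clamp=False) + spvsim.integrate_temporal(
            u2, p, 1 / 90, clamp=False
        )
        assert np.allclose(lhs, rhs, atol=1e-12)
        assert np.abs(lhs - _exact_zoh(u1 + u2, p, 1 / 90)).max() < 0.02 * np.abs(lhs).max()

    def test_20hz_preset_clamps_to_zero_under_sustained_input(self):
        """With α > τ_n the pre-clamp steady state is negative, so the
        clamped brightness fades to exactly zero."""
        p = spvsim.TemporalParams.preset("20Hz")
        b = spvsim.integrate_temporal(np.ones(40 * 90), p, 1 / 90)
        assert b[-1] == 0.0
        unclamped = spvsim.integrate_temporal(np.ones(40 * 90), p, 1 / 90, clamp=False)
        assert unclamped[-1] < 0.0

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            spvsim.integrate_temporal(np.ones(5), spvsim.TemporalParams(), dt=0.0)
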