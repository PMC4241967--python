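"""Diffusion-weighted signal model, gradient schemes and tensor fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import special_ortho_group

from idti import (
    DegenerateSchemeError,
    GradientScheme,
    InvalidParameterError,
    SequenceParams,
    TensorState,
    b_value,
    default_scheme,
    detectable,
    echo_attenuation,
    fit_tensor,
    fractional_anisotropy,
    relative_signal_drop,
    synthesize_signal,
    uniform_directions,
)
from idti.dwi import GAMMA_PROTON, tensor_from_state


class TestBValue:
    def test_direct_b_passthrough(self):
        assert b_value(SequenceParams(b=600.0)) == 600.0

    def test_formula_against_hand_computation(self):
        # (gamma g delta)^2 (Delta - delta/3) in SI, then s/m^2 -> s/mm^2
        seq = SequenceParams(
            gamma=2.675e8, g_amplitude=30e-3, delta_ms=20.0, Delta_ms=35.0
        )
        expected_si = (2.675e8 * 30e-3 * 0.020) ** 2 * (0.035 - 0.020 / 3)
        assert b_value(seq) == pytest.approx(expected_si / 1e6, rel=1e-12)

    def test_zero_delta_gives_zero(self):
        seq = SequenceParams(g_amplitude=30e-3, delta_ms=0.0, Delta_ms=35.0)
        assert b_value(seq) == 0.0

    def test_doubling_gradient_quadruples_b(self):
        b1 = b_value(SequenceParams(g_amplitude=30e-3, delta_ms=20, Delta_ms=35))
        b2 = b_value(SequenceParams(g_amplitude=60e-3, delta_ms=20, Delta_ms=35))
        assert b2 == pytest.approx(4 * b1, rel=1e-12)

    def test_pulse_overlap_rejected(self):
        with pytest.raises(InvalidParameterError):
            SequenceParams(g_amplitude=30e-3, delta_ms=40.0, Delta_ms=35.0)


class TestAttenuation:
    @pytest.mark.parametrize(
        "b, d, expected",
        [
            (600.0, 2.00e-10, math.exp(-0.12)),
            (0.0, 2.00e-10, 1.0),
            (600.0, 2.128e-10, math.exp(-0.12768)),
        ],
    )
    def test_echo_attenuation(self, b, d, expected):
        assert echo_attenuation(1.0, b, d) == pytest.approx(expected, rel=1e-12)

    def test_published_signal_drop(self):
        """D_perp 2.00 -> 2.13 e-10 at b=600 drops the echo by ~0.77%."""
        drop = relative_signal_drop(600.0, 2.00e-10, 2.13e-10)
        assert 100 * drop == pytest.approx(0.77, abs=0.01)

    def test_exact_mode_counterpart(self):
        drop = relative_signal_drop(600.0, 2.00e-10, 2.120e-10)
        assert 100 * drop == pytest.approx(0.72, abs=0.005)

    def test_equal_diffusivities_no_drop(self):
        assert relative_signal_drop(600.0, 2e-10, 2e-10) == 0.0

    @given(
        b=st.floats(min_value=1.0, max_value=3000),
        dd=st.floats(min_value=1e-13, max_value=5e-11),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_drop_monotone_and_first_order(self, b, dd):
        """Drop grows with b and with dD, and ~= b*dD to first order."""
        d0 = 2e-10
        drop = relative_signal_drop(b, d0, d0 + dd)
        assert drop > 0
        assert relative_signal_drop(2 * b, d0, d0 + dd) > drop
        assert relative_signal_drop(b, d0, d0 + 2 * dd) > drop
        linear = b * dd * 1e6
        assert drop == pytest.approx(linear, rel=2 * linear + 1e-12)


class TestDetectable:
    def test_just_above_limit_at_snr_400(self):
        ok, margin = detectable(0.0077, 400.0, z=3.0)
        assert ok
        assert margin == pytest.approx(0.0002, abs=1e-6)

    def test_zero_drop_not_detectable(self):
        ok, _ = detectable(0.0, 400.0)
        assert not ok

    def test_low_snr_not_detectable(self):
        ok, margin = detectable(0.0077, 100.0, z=3.0)
        assert not ok
        assert margin == pytest.approx(0.0077 - 0.03, abs=1e-9)

    def test_invalid_snr(self):
        with pytest.raises(InvalidParameterError):
            detectable(0.01, 0.0)


class TestGradientScheme:
    def test_default_scheme_shape(self):
        scheme = default_scheme()
        assert len(scheme) == 31
        assert scheme.n_b0 == 1
        norms = np.linalg.norm(scheme.bvecs[scheme.bvals > 0], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_uniform_directions_spread(self):
        """No two of 30 hemisphere directions are nearly collinear."""
        dirs = uniform_directions(30)
        dots = np.abs(dirs @ dirs.T) - np.eye(30)
        assert dots.max() < 0.995

    def test_non_unit_direction_rejected(self):
        with pytest.raises(InvalidParameterError):
            GradientScheme(
                bvals=np.array([600.0]), bvecs=np.array([[2.0, 0.0, 0.0]])
            )

    def test_bval_bvec_round_trip(self, tmp_path):
        scheme = default_scheme()
        scheme.to_bval_bvec(tmp_path / "s.bval", tmp_path / "s.bvec")
        loaded = GradientScheme.from_bval_bvec(
            tmp_path / "s.bval", tmp_path / "s.bvec"
        )
        assert np.allclose(loaded.bvals, scheme.bvals)
        assert np.allclose(loaded.bvecs, scheme.bvecs, atol=1e-7)

    def test_four_column_table_round_trip(self, tmp_path):
        scheme = default_scheme(b=1000.0, n_directions=12)
        scheme.to_table(tmp_path / "scheme.txt")
        loaded = GradientScheme.from_table(tmp_path / "scheme.txt")
        assert np.allclose(loaded.bvals, scheme.bvals)
        assert np.allclose(loaded.bvecs, scheme.bvecs, atol=1e-7)


class TestSynthesizeAndFit:
    def test_perpendicular_gradient_reduces_to_mono_exponential(self):
        """A gradient along the second eigenvector sees exp(-b lambda2)."""
        state = TensorState(1e-9, 2e-10, 2e-10)
        scheme = GradientScheme(
            bvals=np.array([0.0, 600.0, 600.0]),
            bvecs=np.array([[0, 0, 0], [1.0, 0, 0], [0, 0, 1.0]]),
        )
        sig = synthesize_signal(state, scheme, a0=2.0)
        assert sig[0] == pytest.approx(2.0)
        assert sig[1] == pytest.approx(echo_attenuation(2.0, 600.0, 2e-10), rel=1e-12)
        assert sig[2] == pytest.approx(echo_attenuation(2.0, 600.0, 1e-9), rel=1e-12)

    def test_noiseless_round_trip(self):
        state = TensorState(1.3e-9, 4e-10, 2.5e-10)
        scheme = default_scheme()
        axis = np.array([1.0, 2.0, -0.5])
        fitted, _ = fit_tensor(
            synthesize_signal(state, scheme, principal_axis=axis), scheme
        )
        for got, want in zip(fitted.eigenvalues, state.eigenvalues):
            assert got == pytest.approx(want, rel=1e-10)

    def test_isotropic_fit_has_zero_fa(self):
        state = TensorState(7e-10, 7e-10, 7e-10)
        scheme = default_scheme()
        fitted, _ = fit_tensor(synthesize_signal(state, scheme), scheme)
        assert fractional_anisotropy(fitted) == pytest.approx(0.0, abs=1e-9)

    def test_pipeline_closure_fa_change(self, cst_bundle, chans, params):
        """Synthesize inactive/active voxels, refit: FA drop ~= -2.1%."""
        from idti import activation_summary

        res = activation_summary(cst_bundle, chans, params)
        scheme = default_scheme()
        fa = {}
        for name, state in (("inactive", res.inactive), ("active", res.active)):
            fitted, _ = fit_tensor(synthesize_signal(state, scheme), scheme)
            fa[name] = fractional_anisotropy(fitted)
        rel = (fa["active"] - fa["inactive"]) / fa["inactive"]
        assert 100 * rel == pytest.approx(-2.1, abs=0.1)

    def test_rotation_invariance_of_fa(self):
        """FA of the fit is invariant under joint rotation of fiber and scheme."""
        state = TensorState(1e-9, 3e-10, 2e-10)
        scheme = default_scheme()
        fitted0, _ = fit_tensor(synthesize_signal(state, scheme), scheme)
        fa0 = fractional_anisotropy(fitted0)
        rng = np.random.default_rng(42)
        for _ in range(5):
            rot = special_ortho_group.rvs(3, random_state=rng)
            d_rot = rot @ tensor_from_state(state) @ rot.T
            fitted, _ = fit_tensor(synthesize_signal(d_rot, scheme), scheme)
            assert fractional_anisotropy(fitted) == pytest.approx(fa0, abs=1e-6)

    def test_degenerate_scheme_rejected(self):
        scheme = GradientScheme(
            bvals=np.array([0.0] + [600.0] * 6),
            bvecs=np.vstack([[0, 0, 0]] + [[1.0, 0, 0]] * 6),
        )
        with pytest.raises(DegenerateSchemeError):
            fit_tensor(np.ones(7), scheme)

    def test_missing_b0_rejected(self):
        dirs = uniform_directions(8)
        scheme = GradientScheme(bvals=np.full(8, 600.0), bvecs=dirs)
        with pytest.raises(DegenerateSchemeError):
            fit_tensor(np.ones(8), scheme)

    def test_non_positive_signals_masked_with_warning(self):
        state = TensorState(1e-9, 3e-10, 2e-10)
        scheme = default_scheme()
        sig = synthesize_signal(state, scheme)
        sig[5] = -0.01
        with pytest.warns(UserWarning, match="non-positive"):
            fitted, _ = fit_tensor(sig, scheme)
        assert fitted.lambda1 == pytest.approx(1e-9, rel=1e-6)
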