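"""Affine CoM -> state -> kinetics/angles maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comgait.slip_model import (
    AugmentedState,
    TouchdownRefs,
    angle_matrices,
    com_to_outputs,
    default_params,
    kinetics_matrices,
    linearized_state_map,
    state_map_matrices,
    state_to_kinetics,
    state_to_segment_angles,
)
from comgait.slip_model.dynamics import static_kinetics


def z_of(*vals):
    return AugmentedState(np.asarray(vals, float), exact=False)


class TestStateMap:
    def test_offset_cancellation(self, refs):
        z = linearized_state_map(np.array([-refs.alpha, refs.y_hs]), refs)
        np.testing.assert_allclose(z.z, [refs.y_hs, 0.0, 0.0], atol=1e-12)

    def test_zero_alpha_unit_height(self):
        refs = TouchdownRefs(theta_hs=0.0, y_hs=1.0, c_hs=0.0, R=0.0, d=0.0)
        z = linearized_state_map(np.array([0.0, 1.0]), refs)
        np.testing.assert_allclose(z.z, [1.0, 0.0, 0.0], atol=1e-15)

    def test_matches_scalar_expansion(self, refs, rng):
        # oracle: term-by-term scalar expansion of the mapping
        for _ in range(50):
            x1, x2 = rng.uniform(-1, 1), rng.uniform(0.5, 1.5)
            z = linearized_state_map(np.array([x1, x2]), refs)
            expected = (
                x2,
                x1 / refs.y_hs + refs.alpha / refs.y_hs,
                x1 + refs.alpha,
            )
            np.testing.assert_allclose(z.z, expected, rtol=1e-14)

    def test_entry_vocabulary(self, refs):
        W1, b1 = state_map_matrices(refs)
        allowed_w = {0.0, 1.0, 1.0 / refs.y_hs}
        assert set(np.round(W1.ravel(), 12)) <= set(
            np.round(list(allowed_w), 12)
        )
        allowed_b = {0.0, refs.alpha / refs.y_hs, refs.alpha}
        assert set(np.round(b1, 12)) <= set(np.round(list(allowed_b), 12))

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            TouchdownRefs(theta_hs=0.0, y_hs=-1.0, c_hs=0.0)


class TestKineticsMap:
    def test_bias_at_zero_state(self, params):
        _, b2 = kinetics_matrices(params)
        f = state_to_kinetics(z_of(0, 0, 0), params)
        np.testing.assert_allclose(f.f, b2, rtol=1e-14)

    def test_affine_cancellation(self, params, rng):
        W2, _ = kinetics_matrices(params)
        for _ in range(20):
            z1 = rng.uniform(-0.05, 0.05, 3)
            z2 = rng.uniform(-0.05, 0.05, 3)
            lhs = (
                state_to_kinetics(z_of(*(z1 + z2)), params).f
                - state_to_kinetics(z_of(*z2), params).f
            )
            np.testing.assert_allclose(lhs, W2 @ z1, rtol=1e-9, atol=1e-9)

    def test_reference_kinetics_vanish(self, params):
        """At the unloaded vertical configuration the map returns zero."""
        f = state_to_kinetics(z_of(params.l0, 0.0, 0.0), params)
        np.testing.assert_allclose(f.f, 0.0, atol=1e-9)

    def test_halving_perturbation_shrinks_error(self, params):
        """Against the nonlinear force law, error is second order."""

        def nonlinear(eps):
            s = params.l_a - eps
            theta = 0.5 * eps
            fx, fy, ta, _ = static_kinetics(s, theta, params)
            l = s + params.R
            f_lin = state_to_kinetics(z_of(l, theta, l * theta), params).f
            return np.linalg.norm(f_lin - np.array([fx, fy, ta]))

        e1 = nonlinear(1e-2)
        e2 = nonlinear(5e-3)
        assert e2 <= 0.5 * e1 + 1e-12
        e3 = nonlinear(1e-4)
        e4 = nonlinear(5e-5)
        assert e4 <= 0.3 * e3 + 1e-12  # asymptotically quarters


class TestAngleMap:
    def test_affine_cancellation(self, params, rng):
        W3, _ = angle_matrices(params, "stance")
        z_ref = np.array([params.l0, 0.0, 0.0])
        for _ in range(20):
            z1 = rng.uniform(-0.02, 0.02, 3)
            z2 = z_ref + rng.uniform(-0.02, 0.02, 3)
            lhs = (
                state_to_segment_angles(z_of(*(z1 + z2)), params, "stance").theta123
                - state_to_segment_angles(z_of(*z2), params, "stance").theta123
            )
            np.testing.assert_allclose(lhs, W3 @ z1, rtol=1e-9, atol=1e-12)

    def test_stance_swing_differ_only_in_flipped_entries(self, params):
        Ws, bs = angle_matrices(params, "stance")
        Ww, bw = angle_matrices(params, "swing")
        # thigh row identical
        np.testing.assert_allclose(Ws[0], Ww[0])
        assert bs[0] == bw[0]
        # rows 2-3: first weight entry and the bias flip sign
        np.testing.assert_allclose(Ws[1:, 0], -Ww[1:, 0])
        np.testing.assert_allclose(Ws[1:, 1:], Ww[1:, 1:])
        np.testing.assert_allclose(bs[1:], -bw[1:])

    def test_degenerate_lengths_rejected(self, params):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(params, l1=-0.1)

    def test_bad_leg_selector(self, params):
        with pytest.raises(ValueError):
            angle_matrices(params, "hopping")

    def test_thigh_row_matches_inverse_kinematics_first_order(self, params):
        """Relative to the reference configuration, the thigh row agrees
        with exact inverse kinematics at first order."""
        from comgait.slip_model import inverse_kinematics_multibody

        def thigh_ik(s, theta):
            com = np.array([0.0, 0.0])
            ankle = com + s * np.array([np.sin(theta + np.pi), np.cos(theta + np.pi)])
            # ankle below com along the leg direction
            ankle = com - s * np.array([np.sin(theta), np.cos(theta)])
            return inverse_kinematics_multibody(com, ankle, params).theta123[0]

        D0 = params.l0 - params.R
        ref_ik = thigh_ik(D0, 0.0)

        def err(eps):
            s = D0 - eps
            theta = eps
            l = s + params.R
            lin = state_to_segment_angles(
                z_of(l, theta, l * theta), params, "stance"
            ).theta123[0]
            lin_ref = state_to_segment_angles(
                z_of(params.l0, 0.0, 0.0), params, "stance"
            ).theta123[0]
            return abs((lin - lin_ref) - (thigh_ik(s, theta) - ref_ik))

        e1, e2 = err(2e-3), err(1e-3)
        assert e2 <= 0.6 * e1


class TestComposition:
    def test_composition_equivalence(self, params, refs, rng):
        worst = 0.0
        for _ in range(100):
            x = np.array(
                [rng.uniform(-0.08, 0.08) - refs.alpha,
                 refs.y_hs + rng.uniform(-0.05, 0.05)]
            )
            f, ths, thw = com_to_outputs(x, refs, params)
            z = linearized_state_map(x, refs)
            f2 = state_to_kinetics(z, params)
            ths2 = state_to_segment_angles(z, params, "stance")
            thw2 = state_to_segment_angles(z, params, "swing")
            scale = max(1.0, np.max(np.abs(f2.f)))
            worst = max(worst, np.max(np.abs(f.f - f2.f)) / scale)
            worst = max(worst, np.max(np.abs(ths.theta123 - ths2.theta123)))
            worst = max(worst, np.max(np.abs(thw.theta123 - thw2.theta123)))
        assert worst <= 1e-12

    def test_offset_input_reduces_to_reference_kinetics(self, params, refs):
        f, _, _ = com_to_outputs(np.array([-refs.alpha, refs.y_hs]), refs, params)
        expected = state_to_kinetics(z_of(refs.y_hs, 0.0, 0.0), params)
        np.testing.assert_allclose(f.f, expected.f, rtol=1e-12, atol=1e-12)


@settings(max_examples=30, deadline=None)
@given(
    z1=st.tuples(*[st.floats(-0.05, 0.05) for _ in range(3)]),
    z2=st.tuples(*[st.floats(-0.05, 0.05) for _ in range(3)]),
)
def test_superposition_property(z1, z2):
    """Exact superposition after bias cancellation (property over random z)."""
    params = default_params()
    W2, _ = kinetics_matrices(params)
    za, zb = np.array(z1), np.array(z2)
    lhs = (
        state_to_kinetics(z_of(*(za + zb)), params).f
        - state_to_kinetics(z_of(*zb), params).f
    )
    np.testing.assert_allclose(lhs, W2 @ za, rtol=1e-8, atol=1e-8)


def test_linearization_loglog_slope(params):
    """Empirical error slope >= 1.9 over perturbations 1e-4 .. 1e-1."""
    eps = np.logspace(-4, -1, 10)
    errs = []
    for e in eps:
        s = params.l_a - 0.3 * e
        theta = 0.7 * e
        fx, fy, ta, _ = static_kinetics(s, theta, params)
        l = s + params.R
        f_lin = state_to_kinetics(z_of(l, theta, l * theta), params).f
        errs.append(np.linalg.norm(f_lin - np.array([fx, fy, ta])))
    slope = np.polyfit(np.log(eps), np.log(errs), 1)[0]
    assert slope >= 1.9
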