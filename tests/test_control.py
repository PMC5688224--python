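"""Control schemes: task feedback, joint-level distribution, coordination."""

import numpy as np
import pytest

from quietstance import control as ctl
from quietstance.biomechanics import BodyState, dynamics_matrices, forward_task_kinematics
from quietstance.muscle import MuscleParams, activation_and_sensitivity

THETA0 = np.array([-0.1, 0.2, -0.2])
Z = np.zeros(3)


@pytest.fixture(scope="module")
def task(params):
    return forward_task_kinematics(BodyState(THETA0, Z), params)


class TestTaskFeedback:
    def test_zero_estimates_zero_feedback(self):
        g = ctl.ControlGains(o_ref=0.0)
        assert ctl.task_feedback(0.0, 0.0, 0.0, g) == (0.0, 0.0)

    def test_acceleration_gain_derived_from_velocity_gain(self):
        g = ctl.ControlGains(alpha_pdot=12.0, zeta=0.5)
        assert g.alpha_pddot == pytest.approx(np.sqrt(12.0))

    def test_orientation_feedback_arithmetic(self):
        g = ctl.ControlGains(alpha_o=40.0, o_ref=0.0)
        _, f_o = ctl.task_feedback(0.0, 0.0, 0.01, g)
        assert f_o == pytest.approx(-0.4)

    def test_reference_orientation_default_is_reference_posture(self):
        g = ctl.ControlGains()
        _, f_o = ctl.task_feedback(0.0, 0.0, -float(np.sum(g.theta_ref)), g)
        assert f_o == 0.0


class TestSchemeAB:
    def test_scheme_a_zero_feedback(self):
        assert np.allclose(ctl.scheme_A_command(0.0), 0.0)

    def test_scheme_a_ankle_only(self):
        assert np.allclose(ctl.scheme_A_command(0.2), [0.2, 0.0, 0.0])

    def test_scheme_b_zero_at_reference(self):
        g = ctl.ControlGains()
        out = ctl.scheme_B_command(0.0, g.theta_ref, Z, g)
        assert np.allclose(out, 0.0)

    def test_scheme_b_ankle_superposition(self):
        g = ctl.ControlGains()
        th = g.theta_ref + np.array([0.0, 0.05, -0.02])
        base = ctl.scheme_B_command(0.0, th, Z, g)
        plus = ctl.scheme_B_command(0.3, th, Z, g)
        assert plus[0] - base[0] == pytest.approx(0.3)
        assert np.allclose(plus[1:], base[1:])

    def test_scheme_b_proximal_joints_local_only(self):
        g = ctl.ControlGains()
        th = g.theta_ref + np.array([0.1, 0.0, 0.0])  # pure ankle error
        out = ctl.scheme_B_command(0.0, th, Z, g)
        assert np.allclose(out[1:], 0.0)
        assert out[0] == pytest.approx(-g.alpha_theta * 0.1)


class TestSchemeCD:
    def test_zero_feedback_zero_output(self, task):
        fb = ctl.scheme_C_joint_feedback(0.0, 0.0, task)
        assert np.allclose(fb.F, 0.0)

    def test_scheme_c_orientation_leaves_com_unchanged(self, task):
        fb = ctl.scheme_C_joint_feedback(0.0, 0.7, task)
        assert abs(task.J_c @ fb.F_o) <= 1e-10
        assert task.J_o @ fb.F_o == pytest.approx(0.7, rel=1e-10)

    def test_scheme_c_task_force_is_ankle_only(self, task):
        fb = ctl.scheme_C_joint_feedback(0.5, 0.0, task)
        assert fb.F_p[1] == 0.0 and fb.F_p[2] == 0.0
        assert task.J_p[0] * fb.F_p[0] == pytest.approx(0.5)

    def test_scheme_d_satisfies_task_constraint(self, task):
        fb = ctl.scheme_D_joint_feedback(0.37, 0.0, task)
        assert task.J_p @ fb.F_p == pytest.approx(0.37, abs=1e-10)
        assert np.allclose(ctl.scheme_D_joint_feedback(0.0, 0.0, task).F_p, 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_scheme_d_minimum_norm(self, params, seed):
        """D's pseudo-inverse solution is never longer than C's ankle-only
        solution for the same task feedback."""
        rng = np.random.default_rng(seed)
        for _ in range(250):
            th = THETA0 + rng.uniform(-0.4, 0.4, 3)
            tk = forward_task_kinematics(BodyState(th, Z), params)
            f_p = rng.normal(0, 1)
            fc = ctl.scheme_C_joint_feedback(f_p, 0.0, tk)
            fd = ctl.scheme_D_joint_feedback(f_p, 0.0, tk)
            assert np.linalg.norm(fd.F_p) <= np.linalg.norm(fc.F_p) + 1e-12


class TestActivationSensitivity:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_finite_differences(self, muscle_params, seed):
        rng = np.random.default_rng(seed)
        th_hat = rng.normal(0, 0.1, 3)
        thd_hat = rng.normal(0, 0.2, 3)
        lam = rng.normal(0, 0.1, 3)
        lam_dot = rng.normal(0, 0.1, 3)
        R = ctl.activation_sensitivity(th_hat, thd_hat, lam, lam_dot,
                                       muscle_params)
        eps = 1e-7
        for j in range(3):
            e = np.zeros(3); e[j] = eps
            up, _ = activation_and_sensitivity(th_hat, thd_hat, lam + e,
                                               lam_dot, muscle_params)
            dn, _ = activation_and_sensitivity(th_hat, thd_hat, lam - e,
                                               lam_dot, muscle_params)
            fd = (up[j] - dn[j]) / (2 * eps)
            assert R[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_below_saturation_formula(self, muscle_params):
        """Away from saturation R_jj = alpha_E [(E_AG+1) + (E_AN+1)]."""
        from quietstance.muscle import motoneuron_activation

        e_ag, e_an = motoneuron_activation(Z, Z, Z, Z, muscle_params)
        R = ctl.activation_sensitivity(Z, Z, Z, Z, muscle_params)
        expected = muscle_params.alpha_E * ((e_ag + 1) + (e_an + 1))
        assert np.allclose(R, expected)
        assert np.all(R > 0)

    def test_sensitivity_grows_with_cocontraction(self):
        vals = []
        for rho in (0.01, 0.05, 0.1):
            p = MuscleParams(rho=np.full(3, rho))
            vals.append(ctl.activation_sensitivity(Z, Z, Z, Z, p)[0])
        assert vals[0] < vals[1] < vals[2]


class TestCoordinationTransform:
    def test_zero_force_zero_command(self, muscle_params, params):
        M = dynamics_matrices(BodyState(THETA0, Z), params).M
        R = ctl.activation_sensitivity(Z, Z, Z, Z, muscle_params)
        out = ctl.coordination_transform(Z, R, M, muscle_params)
        assert np.allclose(out, 0.0)

    def test_linearity(self, muscle_params, params):
        M = dynamics_matrices(BodyState(THETA0, Z), params).M
        R = ctl.activation_sensitivity(Z, Z, Z, Z, muscle_params)
        F = np.array([0.2, -0.1, 0.4])
        one = ctl.coordination_transform(F, R, M, muscle_params)
        two = ctl.coordination_transform(2 * F, R, M, muscle_params)
        assert np.allclose(two, 2 * one)

    def test_round_trip_matrix_identity(self, muscle_params, params):
        """A R lambda_dot recovers M F (the inverse-model calibration)."""
        M = dynamics_matrices(BodyState(THETA0, Z), params).M
        R = ctl.activation_sensitivity(Z, Z, Z, Z, muscle_params)
        F = np.array([0.3, 0.1, -0.2])
        lam_dot = ctl.coordination_transform(F, R, M, muscle_params)
        assert np.allclose(muscle_params.A @ (R * lam_dot), M @ F, atol=1e-10)


class TestDispatch:
    @pytest.mark.parametrize("scheme", ctl.SCHEMES)
    def test_no_drive_at_fixed_point(self, scheme, params, muscle_params, task):
        """With the body at the reference state and zero noise, every scheme
        outputs a zero threshold-rate command."""
        g = ctl.ControlGains(scheme=scheme)
        M = dynamics_matrices(BodyState(THETA0, Z), params).M
        lam = THETA0.copy()  # passive-balanced operating point
        f_p, f_o = ctl.task_feedback(0.0, 0.0, -float(np.sum(g.theta_ref)), g)
        out = ctl.descending_command(scheme, f_p, f_o, task, THETA0, Z, Z,
                                     lam, Z, M, g, muscle_params)
        assert np.allclose(out, 0.0, atol=1e-14)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            ctl.ControlGains(scheme="E")
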