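"""Lambda-model muscle pairs: reflex activation, torque generation, passive
torques and threshold initialisation."""

import math

import numpy as np
import pytest
from scipy.optimize import bisect

from quietstance import muscle as mm
from quietstance.biomechanics import BodyState, dynamics_matrices

THETA0 = np.array([-0.1, 0.2, -0.2])
Z = np.zeros(3)


class TestMotoneuronActivation:
    def test_zero_at_threshold_minus_cocontraction(self, muscle_params):
        lam = THETA0 + muscle_params.rho  # theta = lam - rho => AG arg zero
        e_ag, _ = mm.motoneuron_activation(THETA0, Z, lam, Z, muscle_params)
        assert np.allclose(e_ag, 0.0)

    def test_symmetric_cocontraction_value(self, muscle_params):
        """At threshold with rho = 0.01 and alpha_E = 12 both pools sit at
        exp(0.12) - 1."""
        e_ag, e_an = mm.motoneuron_activation(THETA0, Z, THETA0, Z, muscle_params)
        expected = math.expm1(12 * 0.01)
        assert np.allclose(e_ag, expected, rtol=1e-12)
        assert np.allclose(e_an, expected, rtol=1e-12)

    def test_saturation_branch_continuity_and_asymptote(self, muscle_params):
        p = muscle_params
        # value and slope continuity at the crossover E* = 0.75 E_max
        e_star = p.e_star
        below = e_star - 1e-7
        above = e_star + 1e-7
        f = lambda e: mm._saturate(np.array([e]), p)[0]
        assert f(above) == pytest.approx(f(below), abs=1e-6)
        slope_above = (f(above + 1e-4) - f(above)) / 1e-4
        assert slope_above == pytest.approx(1.0, abs=1e-2)
        # asymptote: large raw activation approaches but never reaches E_max
        big = f(1e9)
        assert big < p.E_max
        assert big == pytest.approx(p.E_max, abs=1e-6)

    def test_output_bounded_by_emax(self, muscle_params):
        rng = np.random.default_rng(0)
        for _ in range(200):
            th = rng.normal(0, 2, 3)
            thd = rng.normal(0, 10, 3)
            e_ag, e_an = mm.motoneuron_activation(th, thd, Z, Z, muscle_params)
            assert np.all(e_ag >= 0) and np.all(e_ag < muscle_params.E_max)
            assert np.all(e_an >= 0) and np.all(e_an < muscle_params.E_max)

    def test_monotone_in_sensed_angle(self, muscle_params):
        grid = np.linspace(-0.5, 0.5, 101)
        ag = [mm.motoneuron_activation(np.full(3, x), Z, Z, Z, muscle_params)[0][0]
              for x in grid]
        an = [mm.motoneuron_activation(np.full(3, x), Z, Z, Z, muscle_params)[1][0]
              for x in grid]
        assert np.all(np.diff(ag) >= 0)
        assert np.all(np.diff(an) <= 0)


class TestNetActivationAndTorque:
    def test_symmetric_cocontraction_cancels(self):
        e = np.array([2.0, 3.0, 1.0])
        assert np.allclose(mm.net_activation(e, e, np.array([0.7, 1.3, 1.0])), 0)

    def test_identity_case(self):
        out = mm.net_activation(Z, np.array([1.0, 0, 0]), np.ones(3))
        assert np.allclose(out, [1.0, 0, 0])

    def test_motor_noise_mean_is_one(self):
        rng = np.random.default_rng(7)
        eta = np.maximum(1.0 + 0.01 * rng.standard_normal(10 ** 5), 0.0)
        assert abs(eta.mean() - 1.0) <= 3e-4

    def test_distribution_matrix_columns(self, muscle_params):
        """Unit activations reproduce the printed muscle distribution
        columns, including the biarticular couplings."""
        t1 = mm.steady_state_torque(np.array([1.0, 0, 0]), muscle_params)
        t2 = mm.steady_state_torque(np.array([0, 1.0, 0]), muscle_params)
        assert np.allclose(t1, [10.94, 0.0, 0.0])
        assert np.allclose(t2, [1.1, 7.43, 0.94])
        assert np.allclose(mm.steady_state_torque(Z, muscle_params), 0.0)


class TestTorqueFilter:
    def test_step_response_matches_closed_form(self, muscle_params):
        """Critically damped second order: 1 - (1 + t/tau) exp(-t/tau)."""
        p = muscle_params
        target = np.array([10.0, -5.0, 2.0])
        state = mm.MuscleState(lam=Z.copy(), T_act=Z.copy(), T_act_dot=Z.copy())
        dt = 0.002
        n = int(round(5 * p.tau_m / dt))
        for _ in range(n):
            state = mm.torque_filter_step(state, target, dt, p)
        x = n * dt / p.tau_m
        expected = target * (1 - (1 + x) * math.exp(-x))
        # first-order Euler at dt = 2 ms leaves ~0.7% of the step amplitude
        assert np.allclose(state.T_act, expected, rtol=1e-2)

    def test_fixed_point(self, muscle_params):
        state = mm.MuscleState(lam=Z, T_act=np.array([3.0, 1.0, -2.0]),
                               T_act_dot=Z.copy())
        out = mm.torque_filter_step(state, state.T_act, 0.002, muscle_params)
        assert np.allclose(out.T_act, state.T_act)
        assert np.allclose(out.T_act_dot, 0.0)

    def test_rejects_nonpositive_dt(self, muscle_params):
        state = mm.MuscleState(lam=Z, T_act=Z, T_act_dot=Z)
        with pytest.raises(ValueError):
            mm.torque_filter_step(state, Z, 0.0, muscle_params)


class TestPassiveTorques:
    def test_equal_exponentials_cancel(self):
        coeff = {j: {"exp1": {"const": 1.0, "ankle": 0.1, "knee": -0.2, "hip": 0.05},
                     "exp2": {"const": 1.0, "ankle": 0.1, "knee": -0.2, "hip": 0.05},
                     "offset": 0.0}
                 for j in ("ankle", "knee", "hip")}
        pp = mm.PassiveElasticParams(coefficients=coeff)
        rng = np.random.default_rng(2)
        for _ in range(10):
            assert np.allclose(
                mm.passive_elastic_torque(rng.normal(0, 0.3, 3), pp), 0.0)

    def test_knee_hardstop_resists_extension(self, passive):
        """Knee torque rises steeply and monotonically toward full
        extension (flexion-direction moment against hyperextension)."""
        knee_angles = np.linspace(0.3, -0.3, 25)  # flexed -> hyperextended
        torques = [mm.passive_elastic_torque(np.array([0.0, k, 0.0]), passive)[1]
                   for k in knee_angles]
        diffs = np.diff(torques)
        assert np.all(diffs > 0)
        assert torques[-1] > torques[0] + 20.0  # steep rise, N m

    def test_restoring_slopes_at_stance_posture(self, passive):
        """Each joint's passive stiffness is restoring around upright."""
        eps = 1e-5
        for j in range(3):
            e = np.zeros(3); e[j] = eps
            slope = (mm.passive_elastic_torque(THETA0 + e, passive)[j]
                     - mm.passive_elastic_torque(THETA0 - e, passive)[j]) / (2 * eps)
            assert slope < 0

    def test_matches_independent_reimplementation(self, passive):
        """Dual-implementation oracle: evaluate the double-exponential law
        directly from the shipped coefficient asset at spot postures."""
        anat_sign = np.array([1.0, 1.0, -1.0])
        rng = np.random.default_rng(5)
        for _ in range(5):
            theta = rng.normal(0, 0.15, 3)
            ang = anat_sign * theta * 180.0 / math.pi
            expected = np.empty(3)
            for j, name in enumerate(("ankle", "knee", "hip")):
                c = passive.coefficients[name]
                val = (math.exp(c["exp1"]["const"] + c["exp1"]["ankle"] * ang[0]
                                + c["exp1"]["knee"] * ang[1] + c["exp1"]["hip"] * ang[2])
                       - math.exp(c["exp2"]["const"] + c["exp2"]["ankle"] * ang[0]
                                  + c["exp2"]["knee"] * ang[1] + c["exp2"]["hip"] * ang[2])
                       + c["offset"])
                if name == "knee":
                    val += math.exp(c["hardstop"]["const"]
                                    + c["hardstop"]["knee"] * ang[1])
                expected[j] = anat_sign[j] * val
            assert np.allclose(mm.passive_elastic_torque(theta, passive), expected)

    def test_referenced_field_hits_target(self, passive):
        target = np.array([5.0, -2.0, 1.0])
        ref = passive.referenced(THETA0, target_torque=target)
        assert np.allclose(mm.passive_elastic_torque(THETA0, ref), target,
                           atol=1e-10)


class TestViscousAndTotal:
    def test_damping_matrix_first_column(self, muscle_params):
        out = mm.viscous_torque(np.array([1.0, 0, 0]), muscle_params)
        assert np.allclose(out, [-25.0, 0.0, 0.0])
        assert np.allclose(mm.viscous_torque(Z, muscle_params), 0.0)

    def test_damping_proportional_to_distribution_matrix(self, muscle_params):
        """B has the same zero pattern as A with a single row-independent
        proportionality constant."""
        A, B = muscle_params.A, muscle_params.B
        nz = A != 0
        assert np.array_equal(nz, B != 0)
        ratios = B[nz] / A[nz]
        assert ratios.std() / ratios.mean() < 0.01

    def test_total_torque_is_elementwise_sum(self):
        a, b, c = np.array([1.0, 2, 3]), np.array([-1.0, 0, 4]), np.array([0.5, 0, 0])
        assert np.allclose(mm.total_torque(a, b, c), a + b + c)
        assert np.allclose(mm.total_torque(a, Z, Z), a)


class TestInitialLambda:
    def test_zero_required_activation_gives_lambda_equals_theta(
            self, muscle_params, passive, params):
        """If passive torque alone balances gravity the thresholds coincide
        with the posture (asinh(0) branch)."""
        dyn = dynamics_matrices(BodyState(THETA0, Z), params)
        balanced = passive.referenced(THETA0, target_torque=dyn.N)
        lam = mm.initial_lambda(THETA0, muscle_params, balanced, dyn.N)
        assert np.allclose(lam, THETA0, atol=1e-12)

    def test_round_trip_reproduces_required_activation(
            self, muscle_params, passive, params):
        dyn = dynamics_matrices(BodyState(THETA0, Z), params)
        lam = mm.initial_lambda(THETA0, muscle_params, passive, dyn.N)
        e_ag, e_an = mm.motoneuron_activation(THETA0, Z, lam, Z, muscle_params)
        e_net = mm.net_activation(e_ag, e_an, np.ones(3))
        t_ela = mm.passive_elastic_torque(THETA0, passive)
        e_req = np.linalg.solve(muscle_params.A, dyn.N - t_ela)
        assert np.allclose(e_net, e_req, atol=1e-10)

    @pytest.mark.parametrize("e_req", [-4.0, -0.5, -0.1, 0.0, 0.2, 1.5, 6.0, 8.5])
    def test_agrees_with_bisection_oracle(self, muscle_params, e_req):
        """The closed-form inverse matches a bisection root-finder on the
        monotone activation-threshold relation to 1e-8 rad."""
        p = muscle_params
        theta_j = 0.1

        def net(lam):
            e_ag, e_an = mm.motoneuron_activation(
                np.full(3, theta_j), Z, np.full(3, lam), Z, p)
            return (-e_ag + e_an)[0] - e_req

        lam_closed = mm.invert_net_activation(e_req, theta_j, p.rho[0], p)
        lam_bisect = bisect(net, theta_j - 3.0, theta_j + 3.0, xtol=1e-12)
        assert lam_closed == pytest.approx(lam_bisect, abs=1e-8)

    def test_unreachable_activation_rejected(self, muscle_params):
        with pytest.raises(ValueError):
            mm.invert_net_activation(muscle_params.E_max + 0.1, 0.0, 0.01,
                                     muscle_params)

    def test_net_activation_monotone_in_lambda(self, muscle_params):
        """Invertibility claim: for fixed posture the net activation is a
        monotone function of the threshold."""
        lams = np.linspace(-1.0, 1.0, 401)
        vals = []
        for lam in lams:
            e_ag, e_an = mm.motoneuron_activation(Z, Z, np.full(3, lam), Z,
                                                  muscle_params)
            vals.append((-e_ag + e_an)[0])
        assert np.all(np.diff(vals) >= 0)
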