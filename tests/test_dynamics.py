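import numpy as np
import pytest
from scipy.integrate import solve_ivp

from skitakeoff.dynamics import (
    ExternalLoad,
    forward_dynamics,
    inverse_dynamics,
    com_kinematics,
    mass_matrix,
    rnea,
    whole_body_grf_oracle,
)
from skitakeoff.kinematics import MotionTrajectory
from skitakeoff.tree import CompiledModel

from conftest import make_pendulum

G = 9.81


def _static_motion(comp, q, n=3):
    times = np.arange(n) / 100.0
    Q = np.tile(q, (n, 1))
    Z = np.zeros_like(Q)
    return MotionTrajectory(
        coordinate_names=list(comp.coordinate_names), times=times,
        q=Q, qdot=Z.copy(), qddot=Z.copy(),
    )


class TestPendulum:
    def test_static_pin_torque_matches_closed_form(self, pendulum):
        m, l = 2.0, 0.5
        comp = CompiledModel(pendulum)
        for theta in (0.0, 0.3, 1.2, -0.7):
            q = np.zeros(comp.nq)
            q[-1] = theta
            tau, wrench = rnea(comp, q, np.zeros(comp.nq), np.zeros(comp.nq))
            assert tau[-1] == pytest.approx(m * G * l * np.sin(theta), abs=1e-10)
            # base wrench supports the full weight when static
            assert wrench[1] == pytest.approx((m + 1.0) * G, abs=1e-10)

    def test_balanced_torque_gives_zero_acceleration(self, pendulum):
        comp = CompiledModel(pendulum)
        q = np.zeros(comp.nq)
        q[-1] = 0.4
        tau, _ = rnea(comp, q, np.zeros(comp.nq), np.zeros(comp.nq))
        qdd = forward_dynamics(comp, q, np.zeros(comp.nq), tau)
        np.testing.assert_allclose(qdd, 0.0, atol=1e-9)

    def test_energy_conservation_over_takeoff_window(self, pendulum):
        """Conservative swing: total energy drift < 1e-6 relative in 0.1 s."""
        m, l = 2.0, 0.5
        comp = CompiledModel(pendulum)
        nq = comp.nq

        def rhs(t, y):
            # base held fixed: reduced equation in the pin coordinate only
            th, thd = y
            q = np.zeros(nq); q[-1] = th
            qd = np.zeros(nq); qd[-1] = thd
            c = rnea(comp, q, qd, np.zeros(nq))[0][-1]
            m_pp = mass_matrix(comp, q)[-1, -1]
            return [thd, -c / m_pp]

        sol = solve_ivp(rhs, (0.0, 0.1), [1.0, 0.0], rtol=1e-9, atol=1e-12)
        assert sol.success

        def energy(th, thd):
            I_rod = 1e-4  # Izz about COM in the fixture
            T = 0.5 * (m * l**2 + I_rod) * thd**2
            V = -m * G * l * np.cos(th)
            return T + V

        e0 = energy(*sol.y[:, 0])
        drift = max(abs(energy(*sol.y[:, k]) - e0)
                    for k in range(sol.y.shape[1]))
        assert drift / abs(e0) < 1e-6


class TestForwardInverseConsistency:
    def test_free_base_zero_torque_accelerates_at_gravity(self, pendulum):
        comp = CompiledModel(pendulum)
        qdd = forward_dynamics(comp, np.zeros(comp.nq), np.zeros(comp.nq),
                               np.zeros(comp.nq))
        np.testing.assert_allclose(qdd[:3], [0.0, -G, 0.0], atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_on_random_states(self, seed, toy_model):
        comp = CompiledModel(toy_model)
        rng = np.random.default_rng(seed)
        q = rng.normal(scale=0.4, size=comp.nq)
        qd = rng.normal(size=comp.nq)
        tau = rng.normal(scale=50.0, size=comp.nq)
        qdd = forward_dynamics(comp, q, qd, tau)
        tau_back, _ = rnea(comp, q, qd, qdd)
        np.testing.assert_allclose(tau_back, tau, atol=1e-8)

    def test_inverse_dynamics_linear_in_qddot(self, toy_model):
        """Superposition: ID(a1 + a2) - ID(0) == [ID(a1)-ID(0)] + [ID(a2)-ID(0)]."""
        comp = CompiledModel(toy_model)
        rng = np.random.default_rng(7)
        q = rng.normal(scale=0.3, size=comp.nq)
        qd = rng.normal(size=comp.nq)
        a1 = rng.normal(size=comp.nq)
        a2 = rng.normal(size=comp.nq)
        t0, _ = rnea(comp, q, qd, np.zeros(comp.nq))
        t1, _ = rnea(comp, q, qd, a1)
        t2, _ = rnea(comp, q, qd, a2)
        t12, _ = rnea(comp, q, qd, a1 + a2)
        np.testing.assert_allclose(t12 - t0, (t1 - t0) + (t2 - t0), atol=1e-8)

    def test_mass_matrix_symmetric_positive_definite(self, toy_model):
        comp = CompiledModel(toy_model)
        rng = np.random.default_rng(3)
        M = mass_matrix(comp, rng.normal(scale=0.3, size=comp.nq))
        np.testing.assert_allclose(M, M.T, atol=1e-10)
        assert np.linalg.eigvalsh(M).min() > 0


class TestResiduals:
    def test_ballistic_motion_has_zero_torques_and_residuals(self, toy_model):
        comp = CompiledModel(toy_model)
        q = np.zeros(comp.nq)
        qdd = np.zeros(comp.nq)
        qdd[1] = -G  # free fall
        times = np.arange(3) / 100
        motion = MotionTrajectory(
            coordinate_names=list(comp.coordinate_names), times=times,
            q=np.tile(q, (3, 1)), qdot=np.zeros((3, comp.nq)),
            qddot=np.tile(qdd, (3, 1)),
        )
        gf = inverse_dynamics(comp, motion)
        np.testing.assert_allclose(gf.tau, 0.0, atol=1e-9)
        np.testing.assert_allclose(gf.residual.data, 0.0, atol=1e-9)

    def test_static_stance_residual_absorbs_body_weight(self, toy_model):
        comp = CompiledModel(toy_model)
        motion = _static_motion(comp, np.zeros(comp.nq))
        gf = inverse_dynamics(comp, motion)
        W = toy_model.total_mass * G
        np.testing.assert_allclose(gf.residual.component("Fy"), W, atol=1e-9)
        np.testing.assert_allclose(gf.residual.component("Fx"), 0.0, atol=1e-9)

    def test_residual_vanishes_when_loads_generate_the_motion(self, takeoff):
        """Round trip: applying the ground-truth GRF leaves ~zero residual."""
        from skitakeoff.grf import grf_external_loads

        model = takeoff.scenario.model
        loads = grf_external_loads(model, takeoff.grf_truth)
        gf = inverse_dynamics(model, takeoff.motion, loads)
        assert np.abs(gf.residual.data).max() < 1e-6


class TestWholeBodyOracle:
    def test_static_stance_equals_weight(self, toy_model):
        comp = CompiledModel(toy_model)
        motion = _static_motion(comp, np.zeros(comp.nq))
        net = whole_body_grf_oracle(comp, motion)
        W = toy_model.total_mass * G
        np.testing.assert_allclose(net, [[0, W, 0]] * 3, atol=1e-9)

    def test_vertical_acceleration_follows_newton(self, toy_model):
        comp = CompiledModel(toy_model)
        a = 3.7
        motion = _static_motion(comp, np.zeros(comp.nq))
        motion.qddot[:, 1] = a
        net = whole_body_grf_oracle(comp, motion)
        W = toy_model.total_mass
        np.testing.assert_allclose(net[:, 1], W * (G + a), atol=1e-9)

    def test_constant_drag_shifts_oracle_by_drag(self, toy_model):
        comp = CompiledModel(toy_model)
        motion = _static_motion(comp, np.zeros(comp.nq))
        D = 85.0
        drag = ExternalLoad(
            segment="torso", force=np.tile([-D, 0, 0], (3, 1)),
            point=np.zeros((3, 3)), point_frame="segment",
        )
        net = whole_body_grf_oracle(comp, motion, [drag])
        np.testing.assert_allclose(net[:, 0], D, atol=1e-9)

    def test_com_accelerations_match_numerical_differentiation(self, takeoff):
        """Recursive accelerations vs second differences of COM positions."""
        comp = CompiledModel(takeoff.scenario.model)
        kin = com_kinematics(comp, takeoff.motion)
        t = takeoff.motion.times
        num = np.gradient(np.gradient(kin["com"], t, axis=0), t, axis=0)
        # central differences of a smooth quintic: interior agreement ~1e-2
        assert np.abs(num[2:-2] - kin["com_acc"][2:-2]).max() < 0.5


class TestExternalLoadValidation:
    def test_frame_misalignment_raises(self, toy_model):
        comp = CompiledModel(toy_model)
        motion = _static_motion(comp, np.zeros(comp.nq), n=4)
        bad = ExternalLoad(segment="torso", force=np.zeros((2, 3)),
                           point=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="frames"):
            inverse_dynamics(comp, motion, [bad])

    def test_nonfinite_load_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExternalLoad(segment="torso", force=np.array([[np.nan, 0, 0]]),
                         point=np.zeros((1, 3)))

    def test_missing_accelerations_rejected(self, toy_model):
        comp = CompiledModel(toy_model)
        motion = _static_motion(comp, np.zeros(comp.nq))
        motion.qddot = None
        with pytest.raises(ValueError, match="qddot"):
            inverse_dynamics(comp, motion)
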