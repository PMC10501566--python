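import warnings

import numpy as np
import pytest

from skitakeoff._qp import solve_diag_qp
from skitakeoff.dynamics import GeneralizedForces, ResidualWrench
from skitakeoff.kinematics import MotionTrajectory
from skitakeoff.model import JointDef, ModelDef, Muscle, Segment
from skitakeoff.muscles import (
    moment_arms,
    static_optimization,
    torque_contributions,
)
from skitakeoff.tree import CompiledModel


def two_link(muscles):
    """Base + arm on a z-pin at the origin of the base segment."""
    return ModelDef(
        segments=[
            Segment("base", mass=5.0, com_offset=np.zeros(3),
                    inertia=0.1 * np.eye(3)),
            Segment("arm", mass=1.0, com_offset=np.array([0.0, -0.2, 0.0]),
                    inertia=np.diag([1e-3, 1e-4, 1e-3])),
        ],
        joints=[
            JointDef("root", "ground", "base", "free6dof"),
            JointDef("pin", "base", "arm", "pin", axis=np.array([0, 0, 1.0])),
        ],
        muscles=muscles,
        name="two_link",
    )


def _motion(model, q_pin, n=2):
    comp = CompiledModel(model)
    q = np.zeros((n, comp.nq))
    q[:, -1] = q_pin
    return MotionTrajectory(
        coordinate_names=list(comp.coordinate_names),
        times=np.arange(n) / 100.0, q=q,
        qdot=np.zeros((n, comp.nq)), qddot=np.zeros((n, comp.nq)),
    )


def _torques(model, motion, values):
    comp = CompiledModel(model)
    tau = np.zeros((motion.n_frames, comp.nq))
    for name, v in values.items():
        tau[:, comp.coordinate_names.index(name)] = v
    return GeneralizedForces(
        coordinate_names=list(comp.coordinate_names), times=motion.times,
        tau=tau, residual=ResidualWrench(np.zeros((motion.n_frames, 6))),
    )


class TestMomentArms:
    def test_symmetric_via_points_match_chord_geometry(self):
        """Points at radius r on both sides of a pin: the path length is the
        chord 2 r sin(q/2), so the tendon-excursion arm is r cos(q/2)."""
        r = 0.1
        m = two_link([Muscle(
            "m", path=[("base", np.array([0.0, r, 0.0])),
                       ("arm", np.array([0.0, r, 0.0]))],
            max_isometric_force=100.0,
        )])
        comp = CompiledModel(m)
        for q_pin in (0.3, 0.8, -0.5):
            q = np.zeros(comp.nq)
            q[-1] = q_pin
            R = moment_arms(comp, q)
            expected = -np.sign(q_pin) * r * np.cos(q_pin / 2)
            assert R[0, -1] == pytest.approx(expected, abs=1e-8)

    def test_non_spanned_coordinates_are_exactly_zero(self, toy_model):
        comp = CompiledModel(toy_model)
        rng = np.random.default_rng(0)
        R = moment_arms(comp, rng.normal(scale=0.3, size=comp.nq))
        i = [m.name for m in toy_model.muscles].index("soleus_r")
        j = comp.coordinate_names.index("knee_angle_l")
        assert R[i, j] == 0.0
        j2 = comp.coordinate_names.index("lumbar_rz")
        assert R[i, j2] == 0.0

    def test_knee_extensor_has_positive_extension_arm(self, toy_model):
        comp = CompiledModel(toy_model)
        q = np.zeros(comp.nq)
        q[comp.coordinate_names.index("knee_angle_r")] = np.deg2rad(-70)
        R = moment_arms(comp, q, muscles=["vaslat_r"],
                        coords=[comp.coordinate_names.index("knee_angle_r")])
        assert R[0, 0] > 0.01  # extension is the positive direction

    def test_degenerate_path_yields_nan_with_warning(self):
        m = two_link([Muscle(
            "m", path=[("base", np.zeros(3)), ("arm", np.zeros(3)),
                       ("arm", np.array([0, -0.1, 0.0]))],
            max_isometric_force=10.0,
        )])
        comp = CompiledModel(m)
        with pytest.warns(UserWarning, match="degenerate"):
            R = moment_arms(comp, np.zeros(comp.nq))
        assert np.isnan(R[0]).all()


class TestStaticOptimization:
    def test_zero_demand_gives_zero_activations(self, takeoff):
        model = takeoff.scenario.model
        motion = takeoff.motion
        torques = _torques(model, motion, {})
        sol = static_optimization(model, motion, torques)
        np.testing.assert_allclose(sol.activations, 0.0, atol=1e-12)
        np.testing.assert_allclose(sol.reserves, 0.0, atol=1e-9)

    def test_single_muscle_closed_form(self):
        fmax, r_att = 500.0, 0.1
        m = two_link([Muscle(
            "m", path=[("base", np.array([0.0, r_att, 0.0])),
                       ("arm", np.array([0.0, r_att, 0.0]))],
            max_isometric_force=fmax,
        )])
        motion = _motion(m, q_pin=0.6)
        comp = CompiledModel(m)
        arm = moment_arms(comp, motion.q[0])[0, -1]
        tau = 0.4 * fmax * arm  # demand feasible with a < 1
        torques = _torques(m, motion, {"pin_angle": tau})
        sol = static_optimization(m, motion, torques, coords=["pin_angle"])
        # exact optimum shares a sliver of demand with the penalized reserve:
        # a = tau * Fr / (Fr^2 + 1/w_res), within 1e-6 of tau / (F r)
        assert sol.activations[0, 0] == pytest.approx(tau / (fmax * arm),
                                                      abs=1e-6)
        assert np.abs(sol.reserves).max() < 1e-3

    def test_two_identical_muscles_share_load_equally(self):
        mk = lambda nm: Muscle(
            nm, path=[("base", np.array([0.0, 0.1, 0.0])),
                      ("arm", np.array([0.0, 0.1, 0.0]))],
            max_isometric_force=400.0,
        )
        m = two_link([mk("a"), mk("b")])
        motion = _motion(m, q_pin=0.5)
        comp = CompiledModel(m)
        arm = moment_arms(comp, motion.q[0])[0, -1]
        torques = _torques(m, motion, {"pin_angle": 0.8 * 400.0 * arm})
        sol = static_optimization(m, motion, torques, coords=["pin_angle"])
        assert sol.activations[0, 0] == pytest.approx(sol.activations[0, 1],
                                                      abs=1e-10)

    def test_square_system_recovers_generating_activations(self, planar_model):
        """Two muscles, two constrained coordinates: unique solution."""
        model = planar_model
        comp = CompiledModel(model)
        motion = _motion(model, q_pin=0.0)
        motion.q[:, comp.coordinate_names.index("knee_angle")] = -0.8
        motion.q[:, comp.coordinate_names.index("ankle_angle")] = -0.2
        rng = np.random.default_rng(5)
        a_true = rng.uniform(0.1, 0.9, size=2)
        fmax = np.array([m.max_isometric_force for m in model.muscles])
        coords = ["knee_angle", "ankle_angle"]
        cidx = [comp.coordinate_names.index(c) for c in coords]
        R = moment_arms(comp, motion.q[0], coords=cidx)
        tau_vals = (a_true * fmax) @ R
        torques = _torques(model, motion,
                           dict(zip(coords, tau_vals)))
        sol = static_optimization(model, motion, torques, coords=coords)
        np.testing.assert_allclose(sol.activations[0], a_true, atol=1e-6)

    def test_torque_balance_and_kkt_on_takeoff(self, takeoff):
        from skitakeoff.grf import GRFConfig, estimate_grf

        model = takeoff.scenario.model
        res = estimate_grf(model, takeoff.motion,
                           config=GRFConfig(mode="takeoff_constrained"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = static_optimization(model, takeoff.motion,
                                      res.generalized_forces)
        assert sol.kkt_residual.max() < 1e-6
        tc = torque_contributions(sol)
        tot = tc["per_muscle"].sum(axis=1) + sol.reserves
        cidx = [res.generalized_forces.coordinate_names.index(c)
                for c in sol.coordinate_names]
        assert np.abs(tot - res.generalized_forces.tau[:, cidx]).max() < 1e-6
        assert sol.activations.min() >= 0.0
        assert sol.activations.max() <= 1.0

    def test_strengthening_never_increases_the_objective(self, takeoff):
        from skitakeoff.grf import GRFConfig, estimate_grf

        model = takeoff.scenario.model
        res = estimate_grf(model, takeoff.motion,
                           config=GRFConfig(mode="takeoff_constrained"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol1 = static_optimization(model, takeoff.motion,
                                       res.generalized_forces)
            stronger = model.copy()
            for mu in stronger.muscles:
                mu.max_isometric_force *= 1.5
            sol2 = static_optimization(stronger, takeoff.motion,
                                       res.generalized_forces)
        assert np.all(sol2.objective <= sol1.objective * (1 + 1e-9))

    def test_infeasible_demand_flows_into_reserves(self):
        fmax = 100.0
        m = two_link([Muscle(
            "m", path=[("base", np.array([0.0, 0.1, 0.0])),
                       ("arm", np.array([0.0, 0.1, 0.0]))],
            max_isometric_force=fmax,
        )])
        motion = _motion(m, q_pin=0.5)
        comp = CompiledModel(m)
        arm = moment_arms(comp, motion.q[0])[0, -1]
        tau = 5.0 * fmax * arm  # far beyond muscle capacity
        torques = _torques(m, motion, {"pin_angle": tau})
        with pytest.warns(UserWarning, match="reserve"):
            sol = static_optimization(m, motion, torques, coords=["pin_angle"])
        assert sol.activations[0, 0] == pytest.approx(1.0)
        assert sol.reserves[0, 0] == pytest.approx(tau - fmax * arm, rel=1e-9)

    def test_flv_mode_modulates_available_force(self, takeoff):
        from skitakeoff.muscles import force_length, force_velocity

        model = takeoff.scenario.model
        motion = takeoff.motion
        torques = _torques(model, motion, {})
        sol = static_optimization(model, motion, torques, force_model="flv")
        assert sol.metadata["force_model"] == "flv"
        # multipliers are bounded and the trivial solution is unchanged
        assert np.all(force_length(sol.path_lengths[0] / 0.1) <= 1.0)
        assert np.all((force_velocity(np.zeros(3)) == 1.0))
        np.testing.assert_allclose(sol.activations, 0.0, atol=1e-12)


class TestTorqueContributions:
    def test_biarticular_muscle_opposite_signs_at_knee_and_hip(self, toy_model):
        comp = CompiledModel(toy_model)
        q = np.zeros(comp.nq)
        q[comp.coordinate_names.index("hip_flexion_r")] = np.deg2rad(60)
        q[comp.coordinate_names.index("knee_angle_r")] = np.deg2rad(-60)
        hip = comp.coordinate_names.index("hip_flexion_r")
        knee = comp.coordinate_names.index("knee_angle_r")
        R = moment_arms(comp, q, muscles=["bflh_r"], coords=[hip, knee])
        # hamstring: hip extensor (negative), knee flexor (negative) — with
        # flexion positive at the hip and extension positive at the knee the
        # contributions at the two joints carry opposite anatomical actions
        assert R[0, 0] < 0 and R[0, 1] < 0

    def test_zero_force_muscle_contributes_nothing(self, takeoff):
        model = takeoff.scenario.model
        torques = _torques(model, takeoff.motion, {})
        sol = static_optimization(model, takeoff.motion, torques)
        tc = torque_contributions(sol)
        np.testing.assert_allclose(tc["per_muscle"], 0.0, atol=1e-12)

    def test_grouped_summaries_sum_members(self, takeoff):
        from skitakeoff.grf import GRFConfig, estimate_grf
        from skitakeoff.muscles import DEFAULT_GROUPS

        model = takeoff.scenario.model
        res = estimate_grf(model, takeoff.motion,
                           config=GRFConfig(mode="takeoff_constrained"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = static_optimization(model, takeoff.motion,
                                      res.generalized_forces)
        tc = torque_contributions(sol, DEFAULT_GROUPS)
        idx = [sol.muscle(m) for m in DEFAULT_GROUPS["knee_extensors"]]
        np.testing.assert_allclose(
            tc["groups"]["knee_extensors"],
            tc["per_muscle"][:, idx, :].sum(axis=1), rtol=1e-12,
        )


class TestDiagQP:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_slsqp_on_random_instances(self, seed):
        from scipy.optimize import minimize

        rng = np.random.default_rng(seed)
        nm, nc = 6, 3
        d = np.concatenate([np.ones(nm), 10.0 * np.ones(nc)])
        A = np.hstack([rng.normal(size=(nc, nm)), np.eye(nc)])
        b = rng.normal(scale=2.0, size=nc)
        lb = np.concatenate([np.zeros(nm), np.full(nc, -np.inf)])
        ub = np.concatenate([np.ones(nm), np.full(nc, np.inf)])
        x, lam = solve_diag_qp(d, A, b, lb, ub)

        ref = minimize(
            lambda z: z @ (d * z), x0=np.zeros(nm + nc),
            jac=lambda z: 2 * d * z, method="SLSQP",
            bounds=list(zip(lb, ub)),
            constraints={"type": "eq", "fun": lambda z: A @ z - b,
                         "jac": lambda z: A},
            options={"ftol": 1e-12, "maxiter": 500},
        )
        assert ref.success
        assert x @ (d * x) <= ref.fun + 1e-8
        np.testing.assert_allclose(A @ x, b, atol=1e-9)
        np.testing.assert_allclose(x, ref.x, atol=1e-5)
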