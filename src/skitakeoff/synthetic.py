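"""Synthetic take-off scenarios and aerodynamic databases with known truth.

The motion generator sweeps the bundled model from a deep crouch to near-full
extension over the 0.1 s take-off window (120 fps) using minimum-jerk joint
profiles, whose first and second derivatives are available in closed form —
so the dynamics consistency of the fixture is limited only by round-off, not
by numerical differentiation.  The ground-truth GRF is derived from the
external wrench the motion requires at the pelvis (one inverse-dynamics call
with no contact loads), split evenly between the two legs with the moment
balance transported to the foot application points; feeding it back through
inverse dynamics leaves residuals at machine precision.

The database generator fills any grid (by default the 278-posture reference
grid) from a smooth analytic whole-body force function, split across the ten
body parts by fixed fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aero import (
    ANGLE_ORDER,
    PART_NAMES,
    REF_HEIGHT,
    REF_RHO,
    REF_SPEED,
    AeroDatabase,
    GridBlock,
    grid_blocks,
)
from .dynamics import ExternalLoad, inverse_dynamics
from .grf import GRFState
from .kinematics import MarkerTrajectory, MotionTrajectory, PostureAngles
from .model import ModelDef, load_model, rotational_mask, toy_model_path
from .tree import CompiledModel

__all__ = [
    "SyntheticScenario",
    "SyntheticTakeoff",
    "minimum_jerk",
    "generate_takeoff_motion",
    "generate_aero_db",
    "default_coefficient_function",
    "DEFAULT_PART_FRACTIONS",
]


def minimum_jerk(
    t: np.ndarray, t0: float, t1: float, q0: float, q1: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk point-to-point profile and its exact derivatives."""
    t = np.asarray(t, dtype=float)
    T = t1 - t0
    s = np.clip((t - t0) / T, 0.0, 1.0)
    dq = q1 - q0
    q = q0 + dq * (10 * s**3 - 15 * s**4 + 6 * s**5)
    qd = dq * (30 * s**2 - 60 * s**3 + 30 * s**4) / T
    qdd = dq * (60 * s - 180 * s**2 + 120 * s**3) / T**2
    return q, qd, qdd


#: crouch -> extension coordinate endpoints (degrees; translations in m).
#: The feet stay flat on the table throughout: since every coordinate follows
#: the same minimum-jerk shape, the ankle endpoints being exactly
#: -(pelvis_rz + hip + knee) keeps the world foot pitch at zero in between,
#: as it is for a jumper whose skis remain on the table until release.
_DEFAULT_PROFILES = {
    "pelvis_ty": (0.59, 0.97),
    "pelvis_rz": (-25.0, -5.0),
    "lumbar_rz": (-50.0, -10.0),
    "hip_flexion_l": (110.0, 20.0),
    "hip_flexion_r": (110.0, 20.0),
    "knee_angle_l": (-70.0, -10.0),
    "knee_angle_r": (-70.0, -10.0),
    "ankle_angle_l": (-15.0, -5.0),
    "ankle_angle_r": (-15.0, -5.0),
}


@dataclass
class SyntheticScenario:
    """Parameters of a generated take-off trial."""

    model: ModelDef | None = None  # default: the bundled 9-segment model
    duration: float = 0.1  # s, take-off window
    rate: float = 120.0  # fps
    approach_speed: float = 23.0  # m/s, along +x
    marker_noise: float = 0.0  # m, isotropic Gaussian sigma
    seed: int = 0
    profiles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PROFILES)
    )
    static: bool = False  # hold the initial pose (no motion)
    #: the extension profile spans duration * profile_overshoot (a full
    #: crouch-to-extension push takes about 0.3 s); the 0.1 s window covers
    #: the accelerating first third of the drive, so the normal force stays
    #: positive throughout, as it must while the skis are on the table
    profile_overshoot: float = 3.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.model is None:
            self.model = load_model(toy_model_path("toy9"))

    def provenance(self) -> dict:
        return {
            "generator": "skitakeoff.synthetic.generate_takeoff_motion",
            "duration_s": self.duration,
            "rate_fps": self.rate,
            "approach_speed_mps": self.approach_speed,
            "marker_noise_m": self.marker_noise,
            "seed": self.seed,
            "static": self.static,
            "profiles": {k: list(v) for k, v in self.profiles.items()},
        }


@dataclass
class SyntheticTakeoff:
    """A generated trial: motion, markers and ground-truth GRF."""

    scenario: SyntheticScenario
    motion: MotionTrajectory  # with exact qdot / qddot
    markers: MarkerTrajectory
    grf_truth: GRFState  # per-leg 12-component ground truth
    net_force: np.ndarray  # (n, 3) ground-truth total ground force


def generate_takeoff_motion(
    scenario: SyntheticScenario | None = None,
    aero_loads: list[ExternalLoad] | None = None,
    feet: tuple[str, str] = ("foot_l", "foot_r"),
    station: str = "proximal_metatarsal",
) -> SyntheticTakeoff:
    """Generate a crouch-to-extension trial with known ground-truth GRF.

    Joint-range violations in the requested profiles raise a generation
    error.  With ``aero_loads`` given (frame-aligned), the ground truth
    accounts for them, as the estimator must.
    """
    sc = scenario or SyntheticScenario()
    model = sc.model
    comp = CompiledModel(model)
    n = int(round(sc.duration * sc.rate)) + 1
    times = np.arange(n) / sc.rate
    rot = rotational_mask(model)
    nq = comp.nq

    q = np.zeros((n, nq))
    qd = np.zeros((n, nq))
    qdd = np.zeros((n, nq))
    ranges = model.coordinate_ranges()
    for cname, (v0, v1) in sc.profiles.items():
        j = comp.coordinate_names.index(cname)
        if rot[j]:
            v0, v1 = np.deg2rad(v0), np.deg2rad(v1)
        if sc.static:
            v1 = v0
        if cname in ranges:
            lo, hi = ranges[cname]
            if not (lo - 1e-9 <= v0 <= hi + 1e-9 and lo - 1e-9 <= v1 <= hi + 1e-9):
                raise ValueError(
                    f"profile for {cname} violates its joint range"
                )
        q[:, j], qd[:, j], qdd[:, j] = minimum_jerk(
            times, 0.0, sc.duration * sc.profile_overshoot, v0, v1
        )
    # constant-velocity travel down the table
    jx = comp.coordinate_names.index("pelvis_tx")
    if not sc.static:
        q[:, jx] = sc.approach_speed * times
        qd[:, jx] = sc.approach_speed

    motion = MotionTrajectory(
        coordinate_names=list(comp.coordinate_names),
        times=times,
        q=q,
        qdot=qd,
        qddot=qdd,
        rotational=rot,
        metadata={"provenance": sc.provenance()},
    )

    # markers from forward kinematics, plus seeded noise
    mnames = list(model.marker_map())
    pos = np.empty((n, len(mnames), 3))
    for f in range(n):
        mp = comp.marker_positions(q[f], mnames)
        pos[f] = [mp[m] for m in mnames]
    rng = np.random.default_rng(sc.seed)
    if sc.marker_noise > 0:
        pos = pos + rng.normal(0.0, sc.marker_noise, size=pos.shape)
    markers = MarkerTrajectory(names=mnames, times=times.copy(), positions=pos)

    # ground truth: required external wrench at the pelvis, split per leg
    gf = inverse_dynamics(comp, motion, aero_loads or [])
    res = gf.residual.data  # (n, 6) [F, M] at pelvis origin, world
    left = np.zeros((n, 6))
    right = np.zeros((n, 6))
    left[:, :3] = 0.5 * res[:, :3]
    right[:, :3] = 0.5 * res[:, :3]
    base_joint = next(j for j in model.joints if j.type == "free6dof")
    for f in range(n):
        Rw, ow = comp.fk(q[f])
        o_p = ow[comp.segment_body[base_joint.child]]
        m_xfer = np.zeros(3)
        for seg, data in zip(feet, (left, right)):
            i = comp.segment_body[seg]
            p = ow[i] + Rw[i] @ np.asarray(model.segment(seg).stations[station])
            m_xfer += np.cross(p - o_p, data[f, :3])
        m_leg = 0.5 * (res[f, 3:] - m_xfer)
        left[f, 3:] = m_leg
        right[f, 3:] = m_leg

    truth = GRFState(times=times.copy(), left=left, right=right)
    return SyntheticTakeoff(
        scenario=sc,
        motion=motion,
        markers=markers,
        grf_truth=truth,
        net_force=res[:, :3].copy(),
    )


# ---------------------------------------------------------------------------
# analytic aerodynamic databases
# ---------------------------------------------------------------------------

#: fixed per-part force fractions (sum to 1): trunk and calves dominate
DEFAULT_PART_FRACTIONS = {
    "trunk": 0.30, "head": 0.06,
    "upperarm_l": 0.04, "upperarm_r": 0.04,
    "forearm_l": 0.04, "forearm_r": 0.04,
    "thigh_l": 0.10, "thigh_r": 0.10,
    "calf_l": 0.14, "calf_r": 0.14,
}


def default_coefficient_function(p: PostureAngles) -> np.ndarray:
    """Smooth whole-body aerodynamic force (N) at reference conditions.

    Drag (−x, against the direction of travel) grows with trunk inclination
    δ3 and knee flexion; lift (+y) grows with the angle of attack.  The
    magnitudes are of the order reported for take-off at 23 m/s (drag tens of
    newtons).
    """
    drag = 20.0 + 0.5 * p.delta3 + 0.1 * (180.0 - p.delta2) \
        + 0.05 * p.delta1 + 0.2 * p.alpha
    lift = 5.0 + 0.1 * p.delta3 + 0.4 * p.alpha + 0.02 * p.theta1
    side = 0.05 * p.theta2
    return np.array([-drag, lift, side])


def generate_aero_db(
    coefficient_function=None,
    blocks: tuple[GridBlock, ...] | None = None,
    part_fractions: dict[str, float] | None = None,
    moment_function=None,
    ref_height: float = REF_HEIGHT,
    ref_speed: float = REF_SPEED,
    ref_rho: float = REF_RHO,
) -> AeroDatabase:
    """Fill a posture grid from an analytic whole-body force function.

    ``coefficient_function(PostureAngles) -> (3,)`` gives the whole-body
    force at reference conditions; per-part forces are fixed fractions of it
    (must sum to 1).  ``moment_function`` optionally does the same for
    moments (default: zero).
    """
    fn = coefficient_function or default_coefficient_function
    blocks = blocks or grid_blocks()
    fr = part_fractions or DEFAULT_PART_FRACTIONS
    if set(fr) != set(PART_NAMES):
        raise ValueError("part_fractions must cover exactly the 10 parts")
    tot = sum(fr.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"part fractions must sum to 1 (got {tot})")

    out = []
    for gb in blocks:
        shape = tuple(len(gb.axes[a]) for a in ANGLE_ORDER)
        data = np.empty(shape + (len(PART_NAMES), 6))
        flat = data.reshape(-1, len(PART_NAMES), 6)
        for k, p in enumerate(gb.postures()):
            F = np.asarray(fn(p), dtype=float)
            M = (
                np.asarray(moment_function(p), dtype=float)
                if moment_function
                else np.zeros(3)
            )
            for i, part in enumerate(PART_NAMES):
                flat[k, i, :3] = fr[part] * F
                flat[k, i, 3:] = fr[part] * M
        out.append((gb, data))
    return AeroDatabase(
        out, ref_height=ref_height, ref_speed=ref_speed, ref_rho=ref_rho,
        provenance="synthetic: analytic coefficient function",
    )
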