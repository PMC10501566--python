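"""Marker trajectories, inverse kinematics, differentiation, posture angles.

Inverse kinematics is solved frame-sequentially as a weighted nonlinear least
squares over the generalized coordinates (warm-started from the previous
frame), the de-facto standard for marker-driven musculoskeletal pipelines.
The seven aerodynamic posture angles (ankle δ1, knee δ2, trunk–thigh δ3,
arm–trunk δ4, ski spread θ1, leg spread θ2 and angle of attack α) are
extracted from marker geometry; they are reported in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt

from .model import ModelDef, rotational_mask
from .tree import CompiledModel

__all__ = [
    "MarkerTrajectory",
    "MotionTrajectory",
    "PostureAngles",
    "UnderdeterminedFrameError",
    "inverse_kinematics",
    "differentiate",
    "extract_posture_angles",
]


class UnderdeterminedFrameError(ValueError):
    """Too few usable markers in a frame to pose the model."""


@dataclass
class MarkerTrajectory:
    """Time series of 3-D marker positions (NaN marks a missing sample)."""

    names: list[str]
    times: np.ndarray  # (n,) s, strictly increasing, uniform
    positions: np.ndarray  # (n, n_markers, 3) m

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) < 3:
            raise ValueError("marker trajectory needs >= 3 frames")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(dts) > 1e-6:
            raise ValueError("frame rate must be constant to 1e-6 s")
        if self.positions.shape != (len(self.times), len(self.names), 3):
            raise ValueError("positions shape mismatch")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.times)))

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def marker(self, name: str) -> np.ndarray:
        return self.positions[:, self.names.index(name), :]


@dataclass
class MotionTrajectory:
    """Generalized-coordinate time series with optional derivatives."""

    coordinate_names: list[str]
    times: np.ndarray  # (n,) s
    q: np.ndarray  # (n, nq); rad for angles, m for translations
    qdot: np.ndarray | None = None
    qddot: np.ndarray | None = None
    rotational: list[bool] | None = None  # per-coordinate angle flag
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.times), len(self.coordinate_names)):
            raise ValueError("q shape mismatch")
        for name in ("qdot", "qddot"):
            v = getattr(self, name)
            if v is not None and np.asarray(v).shape != self.q.shape:
                raise ValueError(f"{name} shape mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.times)))

    def coord(self, name: str) -> np.ndarray:
        return self.q[:, self.coordinate_names.index(name)]


@dataclass
class PostureAngles:
    """The seven posture angles indexing the aerodynamic database (degrees)."""

    delta1: float  # ankle angle
    delta2: float  # knee angle (180 = straight)
    delta3: float  # trunk-thigh angle
    delta4: float  # arm-trunk angle
    theta1: float  # angle between skis
    theta2: float  # angle between legs
    alpha: float  # angle of attack

    def as_dict(self) -> dict[str, float]:
        return {
            "delta1": self.delta1,
            "delta2": self.delta2,
            "delta3": self.delta3,
            "delta4": self.delta4,
            "theta1": self.theta1,
            "theta2": self.theta2,
            "alpha": self.alpha,
        }


# ---------------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------------


def _initial_guess(model: ModelDef) -> np.ndarray:
    q0 = np.zeros(model.n_coordinates)
    ranges = model.coordinate_ranges()
    for i, name in enumerate(model.coordinate_names):
        if name in ranges:
            lo, hi = ranges[name]
            q0[i] = 0.5 * (lo + hi)
    return q0


def inverse_kinematics(
    model: ModelDef,
    markers: MarkerTrajectory,
    weights: dict[str, float] | None = None,
    q0: np.ndarray | None = None,
    max_nfev: int = 200,
) -> MotionTrajectory:
    """Fit generalized coordinates to measured markers, frame by frame.

    Per frame, q minimizes ``sum_i w_i ||model_marker_i(q) - measured_i||^2``
    starting from the previous frame's solution (first frame: ``q0`` or a
    mid-range pose).  Markers that are NaN in a frame are dropped for that
    frame.  Coordinates are clamped to their joint ranges afterwards; clamped
    frames are flagged in the metadata.
    """
    comp = CompiledModel(model)
    mmap = model.marker_map()
    used = [n for n in markers.names if n in mmap]
    if not used:
        raise ValueError("no measured marker exists on the model")
    if weights:
        for n in weights:
            if n not in mmap:
                raise ValueError(f"weighted marker {n!r} not on the model")
    w = np.array([float((weights or {}).get(n, 1.0)) for n in used])
    if np.any(w < 0):
        raise ValueError("marker weights must be positive")
    idx = [markers.names.index(n) for n in used]
    seg_body = [comp.segment_body[mmap[n][0]] for n in used]
    offs = np.array([mmap[n][1] for n in used])

    nq = comp.nq
    n = markers.n_frames
    q_out = np.empty((n, nq))
    rms = np.empty(n)
    flagged: list[int] = []
    q_prev = np.asarray(q0, dtype=float) if q0 is not None else _initial_guess(model)

    for f in range(n):
        meas = markers.positions[f, idx, :]
        ok = np.isfinite(meas).all(axis=1) & (w > 0)
        if ok.sum() < 6:
            raise UnderdeterminedFrameError(
                f"frame {f}: only {int(ok.sum())} usable markers (< 6)"
            )
        sw = np.sqrt(w[ok])
        bodies = [b for b, o in zip(seg_body, ok) if o]
        offsets = offs[ok]
        target = meas[ok]

        def resid(q):
            R, o = comp.fk(q)
            pred = np.array(
                [o[b] + R[b] @ off for b, off in zip(bodies, offsets)]
            )
            return ((pred - target) * sw[:, None]).ravel()

        sol = least_squares(
            resid, q_prev, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=max_nfev,
        )
        if not sol.success:
            flagged.append(f)
            q_out[f] = q_prev  # carry previous frame
        else:
            q_out[f] = sol.x
            q_prev = sol.x
        err = resid(q_out[f]).reshape(-1, 3)
        rms[f] = float(np.sqrt(np.mean(np.sum(err**2, axis=1))))

    # clamp to joint ranges, flagging clamped frames
    ranges = model.coordinate_ranges()
    clamped: list[int] = []
    for i, name in enumerate(comp.coordinate_names):
        if name in ranges:
            lo, hi = ranges[name]
            bad = (q_out[:, i] < lo) | (q_out[:, i] > hi)
            if np.any(bad):
                clamped.extend(np.nonzero(bad)[0].tolist())
                q_out[:, i] = np.clip(q_out[:, i], lo, hi)

    return MotionTrajectory(
        coordinate_names=list(comp.coordinate_names),
        times=markers.times.copy(),
        q=q_out,
        rotational=rotational_mask(model),
        metadata={
            "rms_marker_error": rms,
            "mean_rms_marker_error": float(np.mean(rms)),
            "nonconverged_frames": flagged,
            "clamped_frames": sorted(set(clamped)),
        },
    )


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------


def differentiate(
    motion: MotionTrajectory, cutoff_hz: float | None = 10.0
) -> MotionTrajectory:
    """Low-pass filter q (zero-phase Butterworth) and differentiate twice.

    Central differences in the interior, one-sided at the endpoints.  Pass
    ``cutoff_hz=None`` to skip filtering (already-smooth synthetic data).
    """
    if motion.n_frames < 5:
        raise ValueError("need >= 5 frames to differentiate")
    dt = motion.dt
    fs = 1.0 / dt
    q = motion.q
    if cutoff_hz is not None:
        if cutoff_hz >= fs / 2:
            raise ValueError(
                f"cutoff {cutoff_hz} Hz must be below Nyquist {fs / 2:.3f} Hz"
            )
        b, a = butter(2, cutoff_hz / (fs / 2))
        padlen = min(3 * (max(len(a), len(b)) - 1), motion.n_frames - 1)
        q = filtfilt(b, a, q, axis=0, padlen=padlen)
    qdot = np.gradient(q, dt, axis=0)
    qddot = np.gradient(qdot, dt, axis=0)
    meta = dict(motion.metadata)
    meta["filter"] = {"type": "butterworth2_zero_phase", "cutoff_hz": cutoff_hz}
    return MotionTrajectory(
        coordinate_names=list(motion.coordinate_names),
        times=motion.times.copy(),
        q=q,
        qdot=qdot,
        qddot=qddot,
        rotational=motion.rotational,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# posture angles
# ---------------------------------------------------------------------------

_DEFAULT_POINTS = {
    "hip_l": "hip_l", "hip_r": "hip_r",
    "knee_l": "knee_l", "knee_r": "knee_r",
    "ankle_l": "ankle_l", "ankle_r": "ankle_r",
    "heel_l": "heel_l", "heel_r": "heel_r",
    "toe_l": "toe_l", "toe_r": "toe_r",
    "trunk_top": "c7",
    "arm_l": None, "arm_r": None,
    "shoulder_l": "shoulder_l", "shoulder_r": "shoulder_r",
}


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        warnings.warn("zero-length vector in posture angle; returning NaN")
        return float("nan")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def extract_posture_angles(
    model: ModelDef,
    motion: MotionTrajectory,
    points: dict[str, str | None] | None = None,
    velocity: np.ndarray | None = None,
) -> list[PostureAngles]:
    """Posture angles per frame from model-marker geometry.

    ``points`` maps the anatomical roles used here to model marker names
    (defaults fit the bundled toy models; a missing side falls back to the
    other, so planar single-leg models work too).  ``velocity`` overrides the
    centre-of-mass velocity used for the angle of attack; when the body is at
    rest α is reported as 0.
    """
    comp = CompiledModel(model)
    pmap = dict(_DEFAULT_POINTS)
    if points:
        pmap.update(points)
    have = set(model.marker_map())

    def resolve(role: str) -> str | None:
        name = pmap.get(role)
        if name in have:
            return name
        # bilateral fallback: hip_l -> hip, etc.
        if role.endswith(("_l", "_r")):
            base = role[:-2]
            if pmap.get(base) in have:
                return pmap[base]
            if base in have:
                return base
        return name if name in have else None

    roles = ["hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r",
             "heel_l", "heel_r", "toe_l", "toe_r", "trunk_top",
             "arm_l", "arm_r", "shoulder_l", "shoulder_r"]
    names = {r: resolve(r) for r in roles}
    for r in roles[:11]:
        if names[r] is None:
            raise ValueError(f"no model marker for posture role {r!r}")

    n = motion.n_frames
    # marker world positions per frame
    pos: dict[str, np.ndarray] = {r: np.empty((n, 3)) for r in roles if names[r]}
    com = np.empty((n, 3))
    uniq = sorted({names[r] for r in pos})
    for f in range(n):
        mp = comp.marker_positions(motion.q[f], uniq)
        for r in pos:
            pos[r][f] = mp[names[r]]
        com[f] = comp.com_position(motion.q[f])

    if velocity is None:
        if n >= 2:
            velocity = np.gradient(com, motion.times, axis=0)
        else:  # pragma: no cover
            velocity = np.zeros((n, 3))

    out: list[PostureAngles] = []
    for f in range(n):
        P = {r: pos[r][f] for r in pos}
        hip_mid = 0.5 * (P["hip_l"] + P["hip_r"])
        trunk_up = P["trunk_top"] - hip_mid
        d2 = 0.5 * (
            _angle_deg(P["hip_l"] - P["knee_l"], P["ankle_l"] - P["knee_l"])
            + _angle_deg(P["hip_r"] - P["knee_r"], P["ankle_r"] - P["knee_r"])
        )
        d3 = 0.5 * (
            _angle_deg(trunk_up, P["knee_l"] - P["hip_l"])
            + _angle_deg(trunk_up, P["knee_r"] - P["hip_r"])
        )
        ski_l = P["toe_l"] - P["heel_l"]
        ski_r = P["toe_r"] - P["heel_r"]
        d1 = 0.5 * (
            _angle_deg(P["knee_l"] - P["ankle_l"], ski_l)
            + _angle_deg(P["knee_r"] - P["ankle_r"], ski_r)
        )
        if "arm_l" in P and "shoulder_l" in P:
            trunk_dn_l = hip_mid - P["shoulder_l"]
            trunk_dn_r = hip_mid - P["shoulder_r"]
            d4 = 0.5 * (
                _angle_deg(P["arm_l"] - P["shoulder_l"], trunk_dn_l)
                + _angle_deg(P["arm_r"] - P["shoulder_r"], trunk_dn_r)
            )
        else:
            d4 = 0.0  # arms folded along the trunk (toy models carry no arms)
        t1 = _angle_deg(ski_l, ski_r)
        t2 = _angle_deg(P["ankle_l"] - P["hip_l"], P["ankle_r"] - P["hip_r"])

        # angle of attack: COM velocity direction vs the ski plane
        v = velocity[f]
        speed = np.linalg.norm(v)
        if speed < 1e-9:
            a = 0.0
        else:
            u = ski_l / np.linalg.norm(ski_l) + ski_r / np.linalg.norm(ski_r)
            lat = P["heel_r"] - P["heel_l"]
            nrm = np.cross(u, lat)
            if np.linalg.norm(nrm) < 1e-9:
                nrm = np.cross(u, np.array([0.0, 0.0, 1.0]))
            nrm = nrm / np.linalg.norm(nrm)
            a = float(abs(np.degrees(np.arcsin(np.clip(np.dot(v / speed, nrm), -1, 1)))))
        out.append(
            PostureAngles(
                delta1=d1, delta2=d2, delta3=d3, delta4=d4,
                theta1=t1, theta2=t2, alpha=a,
            )
        )
    return out
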