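"""Inverse and forward dynamics on the compiled kinematic tree.

Inverse dynamics uses the recursive Newton–Euler algorithm over the
elementary-joint decomposition, with the base free joint's transmitted wrench
reported separately as the *residual*: the compensating force/torque at the
pelvis, expressed in the ground frame at the pelvis origin, that reconciles
the motion with the applied loads.  Forward dynamics solves
``M(q) qddot = tau + external - bias`` with the mass matrix assembled from
unit-acceleration inverse-dynamics calls; it serves as the oracle for
round-trip testing and synthetic-data generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._spatial import crf, crm, rot_axis, xform
from .kinematics import MotionTrajectory
from .model import ModelDef
from .tree import CompiledModel

__all__ = [
    "ExternalLoad",
    "ResidualWrench",
    "GeneralizedForces",
    "inverse_dynamics",
    "forward_dynamics",
    "mass_matrix",
    "whole_body_grf_oracle",
    "com_kinematics",
]

WRENCH_COMPONENTS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")


@dataclass
class ExternalLoad:
    """A time series of force/torque applied to one segment.

    Forces and torques are in the ground frame; the application point is in
    the segment frame by default (``point_frame="ground"`` for world points).
    """

    segment: str
    force: np.ndarray  # (n, 3) N
    point: np.ndarray  # (n, 3) m
    torque: np.ndarray | None = None  # (n, 3) N m
    point_frame: str = "segment"
    name: str = ""

    def __post_init__(self):
        self.force = np.atleast_2d(np.asarray(self.force, dtype=float))
        self.point = np.atleast_2d(np.asarray(self.point, dtype=float))
        n = len(self.force)
        if self.torque is None:
            self.torque = np.zeros((n, 3))
        self.torque = np.atleast_2d(np.asarray(self.torque, dtype=float))
        for arr, nm in ((self.force, "force"), (self.point, "point"),
                        (self.torque, "torque")):
            if arr.shape != (n, 3):
                raise ValueError(f"{nm} must be (n, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{nm} contains non-finite values")
        if self.point_frame not in ("segment", "ground"):
            raise ValueError("point_frame must be 'segment' or 'ground'")

    @property
    def n_frames(self) -> int:
        return len(self.force)


@dataclass
class ResidualWrench:
    """Per-frame base residual: [Fx, Fy, Fz, Mx, My, Mz] at the pelvis
    origin in the ground frame (N and N·m)."""

    data: np.ndarray  # (n, 6)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != 6:
            raise ValueError("residual wrench needs exactly 6 components")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("residual wrench contains non-finite values")

    def component(self, name: str) -> np.ndarray:
        return self.data[:, WRENCH_COMPONENTS.index(name)]

    @property
    def forces(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def moments(self) -> np.ndarray:
        return self.data[:, 3:]


@dataclass
class GeneralizedForces:
    """Joint torques/forces per coordinate plus the base residual wrench."""

    coordinate_names: list[str]
    times: np.ndarray
    tau: np.ndarray  # (n, nq)  N m | N
    residual: ResidualWrench
    metadata: dict = field(default_factory=dict)

    def coord(self, name: str) -> np.ndarray:
        return self.tau[:, self.coordinate_names.index(name)]


# ---------------------------------------------------------------------------
# core recursion
# ---------------------------------------------------------------------------


def _joint_geometry(body, q):
    """(E, r, S): frame transform pieces and motion subspace for one body."""
    if body.kind == "rev":
        E = rot_axis(body.axis, q[body.q_index]).T
        r = body.offset
        S = np.concatenate([body.axis, np.zeros(3)])
    elif body.kind == "prism":
        E = np.eye(3)
        r = body.offset + body.axis * q[body.q_index]
        S = np.concatenate([np.zeros(3), body.axis])
    else:  # fixed
        E = np.eye(3)
        r = body.offset
        S = np.zeros(6)
    return E, r, S


def rnea(
    comp: CompiledModel,
    q: np.ndarray,
    qd: np.ndarray,
    qdd: np.ndarray,
    loads: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] | None = None,
    gravity: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One recursive Newton–Euler sweep.

    ``loads`` is a list of (body index, world force, world torque, world
    point).  Returns the generalized forces and the base wrench
    ``[Fx, Fy, Fz, Mx, My, Mz]`` in world coordinates at the base segment
    origin.
    """
    g = comp.gravity if gravity is None else np.asarray(gravity, dtype=float)
    nb = comp.nb
    Rw, ow = comp.fk(q)

    X = np.empty((nb, 6, 6))
    S = np.empty((nb, 6))
    v = np.empty((nb, 6))
    a = np.empty((nb, 6))
    f = np.zeros((nb, 6))
    a0 = np.concatenate([np.zeros(3), -g])  # gravity via base acceleration

    for i, b in enumerate(comp.bodies):
        E, r, Si = _joint_geometry(b, q)
        Xi = xform(E, r)
        X[i], S[i] = Xi, Si
        if b.parent < 0:
            vp, ap = np.zeros(6), a0
        else:
            vp, ap = v[b.parent], a[b.parent]
        if b.q_index is None:
            vJ = np.zeros(6)
            v[i] = Xi @ vp
            a[i] = Xi @ ap
        else:
            vJ = Si * qd[b.q_index]
            v[i] = Xi @ vp + vJ
            a[i] = Xi @ ap + Si * qdd[b.q_index] + crm(v[i]) @ vJ
        if b.inertia is not None:
            Iv = b.inertia @ v[i]
            f[i] = b.inertia @ a[i] + crf(v[i]) @ Iv

    if loads:
        for bi, Fw, Tw, Pw in loads:
            nw = Tw + np.cross(Pw - ow[bi], Fw)
            f[bi] -= np.concatenate([Rw[bi].T @ nw, Rw[bi].T @ Fw])

    tau = np.zeros(comp.nq)
    base_body = None
    base_joint = next(j for j in comp.model.joints if j.type == "free6dof")
    base_body = comp.segment_body[base_joint.child]
    base_wrench_local = None
    for i in range(nb - 1, -1, -1):
        b = comp.bodies[i]
        if i == base_body:
            base_wrench_local = f[i].copy()
        if b.q_index is not None:
            tau[b.q_index] = S[i] @ f[i]
        if b.parent >= 0:
            f[b.parent] += X[i].T @ f[i]

    n_w = Rw[base_body] @ base_wrench_local[:3]
    F_w = Rw[base_body] @ base_wrench_local[3:]
    return tau, np.concatenate([F_w, n_w])


def _frame_loads(
    comp: CompiledModel, loads: list[ExternalLoad], frame: int, q: np.ndarray
):
    if not loads:
        return None
    Rw, ow = comp.fk(q)
    out = []
    for ld in loads:
        bi = comp.segment_body[ld.segment]
        if ld.point_frame == "segment":
            Pw = ow[bi] + Rw[bi] @ ld.point[frame]
        else:
            Pw = ld.point[frame]
        out.append((bi, ld.force[frame], ld.torque[frame], Pw))
    return out


def inverse_dynamics(
    model: ModelDef | CompiledModel,
    motion: MotionTrajectory,
    loads: list[ExternalLoad] | None = None,
) -> GeneralizedForces:
    """Generalized forces and base residual wrench over a motion.

    Requires ``motion.qddot``.  External loads must be frame-aligned with the
    motion.  Joint torques for the base free joint's coordinates are the
    projections of the residual wrench on the elementary base joints; the
    residual itself is reported separately.
    """
    comp = model if isinstance(model, CompiledModel) else CompiledModel(model)
    if motion.qddot is None or motion.qdot is None:
        raise ValueError("motion must carry qdot and qddot (run differentiate)")
    if list(motion.coordinate_names) != list(comp.coordinate_names):
        raise ValueError("motion coordinates do not match the model")
    loads = loads or []
    for ld in loads:
        if ld.n_frames != motion.n_frames:
            raise ValueError(
                f"load on {ld.segment!r}: {ld.n_frames} frames, "
                f"motion has {motion.n_frames}"
            )
    n = motion.n_frames
    tau = np.empty((n, comp.nq))
    res = np.empty((n, 6))
    for fi in range(n):
        fl = _frame_loads(comp, loads, fi, motion.q[fi])
        try:
            tau[fi], res[fi] = rnea(
                comp, motion.q[fi], motion.qdot[fi], motion.qddot[fi], fl
            )
        except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(f"frame {fi}: {e}") from e
    return GeneralizedForces(
        coordinate_names=list(comp.coordinate_names),
        times=motion.times.copy(),
        tau=tau,
        residual=ResidualWrench(res),
    )


# ---------------------------------------------------------------------------
# forward dynamics (oracle)
# ---------------------------------------------------------------------------


def mass_matrix(comp: CompiledModel, q: np.ndarray) -> np.ndarray:
    """Joint-space mass matrix via unit-acceleration inverse dynamics."""
    nq = comp.nq
    M = np.empty((nq, nq))
    zero = np.zeros(nq)
    for i in range(nq):
        e = np.zeros(nq)
        e[i] = 1.0
        M[:, i], _ = rnea(comp, q, zero, e, None, gravity=np.zeros(3))
    return 0.5 * (M + M.T)


def forward_dynamics(
    model: ModelDef | CompiledModel,
    q: np.ndarray,
    qd: np.ndarray,
    tau: np.ndarray,
    loads: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Accelerations from applied generalized forces and external loads.

    ``loads`` entries are (segment, world force, world torque, world point).
    """
    comp = model if isinstance(model, CompiledModel) else CompiledModel(model)
    body_loads = None
    if loads:
        body_loads = [
            (comp.segment_body[seg], np.asarray(F, float), np.asarray(T, float),
             np.asarray(P, float))
            for seg, F, T, P in loads
        ]
    bias, _ = rnea(comp, q, qd, np.zeros(comp.nq), body_loads)
    M = mass_matrix(comp, q)
    try:
        return np.linalg.solve(M, np.asarray(tau, dtype=float) - bias)
    except np.linalg.LinAlgError as e:
        degenerate = [
            s.name for s in comp.model.segments
            if np.linalg.eigvalsh(np.asarray(s.inertia)).min() <= 0
        ]
        raise np.linalg.LinAlgError(
            f"singular mass matrix (degenerate inertia in segments {degenerate})"
        ) from e


# ---------------------------------------------------------------------------
# whole-body Newton–Euler oracle
# ---------------------------------------------------------------------------


def com_kinematics(
    comp: CompiledModel, motion: MotionTrajectory
) -> dict[str, np.ndarray]:
    """Per-segment COM world positions/accelerations and whole-body COM.

    Accelerations come from the exact velocity/acceleration recursion (no
    numerical differentiation), so they are consistent with ``motion.qddot``.
    """
    n = motion.n_frames
    segs = [s.name for s in comp.model.segments]
    pos = {s: np.empty((n, 3)) for s in segs}
    acc = {s: np.empty((n, 3)) for s in segs}
    for fi in range(n):
        q, qd, qdd = motion.q[fi], motion.qdot[fi], motion.qddot[fi]
        Rw, ow = comp.fk(q)
        v = np.empty((comp.nb, 6))
        a = np.empty((comp.nb, 6))
        for i, b in enumerate(comp.bodies):
            E, r, S = _joint_geometry(b, q)
            X = xform(E, r)
            vp = np.zeros(6) if b.parent < 0 else v[b.parent]
            ap = np.zeros(6) if b.parent < 0 else a[b.parent]
            if b.q_index is None:
                v[i] = X @ vp
                a[i] = X @ ap
            else:
                vJ = S * qd[b.q_index]
                v[i] = X @ vp + vJ
                a[i] = X @ ap + S * qdd[b.q_index] + crm(v[i]) @ vJ
        for s in segs:
            i = comp.segment_body[s]
            c = comp.bodies[i].com
            w, vo = v[i][:3], v[i][3:]
            al, ao = a[i][:3], a[i][3:]
            a_c = ao + np.cross(al, c) + np.cross(w, vo + np.cross(w, c))
            acc[s][fi] = Rw[i] @ a_c
            pos[s][fi] = ow[i] + Rw[i] @ c
    masses = {s.name: s.mass for s in comp.model.segments}
    total = sum(masses.values())
    com = sum(masses[s] * pos[s] for s in segs) / total
    com_acc = sum(masses[s] * acc[s] for s in segs) / total
    return {
        "segment_com": pos,
        "segment_com_acc": acc,
        "com": com,
        "com_acc": com_acc,
        "total_mass": total,
    }


def whole_body_grf_oracle(
    model: ModelDef | CompiledModel,
    motion: MotionTrajectory,
    aero_loads: list[ExternalLoad] | None = None,
) -> np.ndarray:
    """Net ground force per frame from the whole-body force balance.

    ``F_net = sum_k m_k (a_k - g) - sum(aero forces)`` — a brute-force check
    entirely independent of the iterative estimator's update rule.
    """
    comp = model if isinstance(model, CompiledModel) else CompiledModel(model)
    if motion.qddot is None:
        raise ValueError("motion must carry qddot")
    kin = com_kinematics(comp, motion)
    g = comp.gravity
    net = np.zeros((motion.n_frames, 3))
    for s in comp.model.segments:
        net += s.mass * (kin["segment_com_acc"][s.name] - g)
    for ld in aero_loads or []:
        net -= ld.force
    return net
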