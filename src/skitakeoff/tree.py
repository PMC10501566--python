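"""Compiled kinematic tree: forward kinematics over elementary joints.

A :class:`ModelDef` is flattened into a chain of elementary one-DoF joints
(revolute / prismatic / fixed) connected by massless virtual bodies:

* ``free6dof`` -> prismatic x, y, z (ground-aligned) then revolute x, y, z
  (intrinsic X-Y-Z Euler rotations),
* ``ball``     -> revolute x, y, z,
* ``pin``      -> one revolute about the joint axis,
* ``locked``   -> a fixed transform contributing no coordinates.

The last elementary body of each joint carries the child segment's inertia.
Generalized coordinates are ordered by joint document order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._spatial import rot_axis, spatial_inertia
from .model import ModelDef

__all__ = ["ElemJoint", "CompiledModel", "compile_model"]

_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


@dataclass
class ElemJoint:
    parent: int  # elementary body index, -1 = ground
    offset: np.ndarray  # child origin in parent frame (before joint motion)
    kind: str  # "rev" | "prism" | "fixed"
    axis: np.ndarray  # in the local (pre-motion) frame; unit
    q_index: int | None  # generalized coordinate index; None for fixed
    segment: str | None  # segment name if this body is a real segment
    inertia: np.ndarray | None  # 6x6 spatial inertia (real segments only)
    mass: float = 0.0
    com: np.ndarray | None = None  # COM offset in body frame (real segments)


class CompiledModel:
    """Flattened tree with cached structure for kinematics and dynamics."""

    def __init__(self, model: ModelDef):
        model.validate()
        self.model = model
        self.bodies: list[ElemJoint] = []
        self.coordinate_names: list[str] = []
        self.segment_body: dict[str, int] = {}
        self._build()
        self.nq = len(self.coordinate_names)
        self.nb = len(self.bodies)
        self.gravity = np.asarray(model.gravity, dtype=float)

    # -- construction ------------------------------------------------------

    def _build(self) -> None:
        joints_by_parent: dict[str, list] = {}
        for j in self.model.joints:
            joints_by_parent.setdefault(j.parent, []).append(j)
        # breadth-first from ground, preserving document order within a parent
        order = []
        stack = ["ground"]
        while stack:
            parent = stack.pop(0)
            for j in joints_by_parent.get(parent, []):
                order.append(j)
                stack.append(j.child)

        for j in order:
            parent_body = -1 if j.parent == "ground" else self.segment_body[j.parent]
            seg = self.model.segment(j.child)
            cnames = j.coordinate_names()
            if j.type == "free6dof":
                elems = [("prism", _AXES[a]) for a in "xyz"] + [
                    ("rev", _AXES[a]) for a in "xyz"
                ]
            elif j.type == "ball":
                elems = [("rev", _AXES[a]) for a in "xyz"]
            elif j.type == "pin":
                ax = np.asarray(j.axis, dtype=float)
                elems = [("rev", ax / np.linalg.norm(ax))]
            else:  # locked
                elems = [("fixed", _AXES["z"])]

            p = parent_body
            for k, (kind, axis) in enumerate(elems):
                offset = (
                    np.asarray(j.location_in_parent, dtype=float)
                    if k == 0
                    else np.zeros(3)
                )
                last = k == len(elems) - 1
                if kind == "fixed":
                    q_index = None
                else:
                    q_index = len(self.coordinate_names)
                    self.coordinate_names.append(cnames[k])
                body = ElemJoint(
                    parent=p,
                    offset=offset,
                    kind=kind,
                    axis=axis,
                    q_index=q_index,
                    segment=j.child if last else None,
                    inertia=(
                        spatial_inertia(seg.mass, seg.com_offset, seg.inertia)
                        if last
                        else None
                    ),
                    mass=seg.mass if last else 0.0,
                    com=np.asarray(seg.com_offset, dtype=float) if last else None,
                )
                self.bodies.append(body)
                p = len(self.bodies) - 1
            self.segment_body[j.child] = p

    # -- forward kinematics ------------------------------------------------

    def fk(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """World pose of every elementary body.

        Returns ``(R, o)`` with ``R[i]`` the body-to-world rotation and
        ``o[i]`` the body origin in world coordinates.
        """
        q = np.asarray(q, dtype=float)
        R = np.empty((self.nb, 3, 3))
        o = np.empty((self.nb, 3))
        for i, b in enumerate(self.bodies):
            Rp = np.eye(3) if b.parent < 0 else R[b.parent]
            op = np.zeros(3) if b.parent < 0 else o[b.parent]
            if b.kind == "rev":
                R[i] = Rp @ rot_axis(b.axis, q[b.q_index])
                o[i] = op + Rp @ b.offset
            elif b.kind == "prism":
                R[i] = Rp
                o[i] = op + Rp @ (b.offset + b.axis * q[b.q_index])
            else:
                R[i] = Rp
                o[i] = op + Rp @ b.offset
        return R, o

    def segment_pose(self, q: np.ndarray, segment: str) -> tuple[np.ndarray, np.ndarray]:
        R, o = self.fk(q)
        i = self.segment_body[segment]
        return R[i], o[i]

    def world_point(
        self, q: np.ndarray, segment: str, point: np.ndarray,
        fk: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> np.ndarray:
        R, o = fk if fk is not None else self.fk(q)
        i = self.segment_body[segment]
        return o[i] + R[i] @ np.asarray(point, dtype=float)

    def marker_positions(
        self, q: np.ndarray, names: list[str] | None = None
    ) -> dict[str, np.ndarray]:
        mmap = self.model.marker_map()
        if names is None:
            names = list(mmap)
        R, o = self.fk(q)
        out = {}
        for n in names:
            seg, off = mmap[n]
            i = self.segment_body[seg]
            out[n] = o[i] + R[i] @ off
        return out

    def com_position(self, q: np.ndarray) -> np.ndarray:
        """Whole-body centre of mass in world coordinates."""
        R, o = self.fk(q)
        tot = 0.0
        acc = np.zeros(3)
        for i, b in enumerate(self.bodies):
            if b.mass > 0:
                acc += b.mass * (o[i] + R[i] @ b.com)
                tot += b.mass
        return acc / tot

    def path_length(self, q: np.ndarray, muscle_name: str) -> float:
        """Total straight-line length of a muscle's via-point path."""
        m = next(m for m in self.model.muscles if m.name == muscle_name)
        R, o = self.fk(q)
        pts = []
        for seg, pt in m.path:
            i = self.segment_body[seg]
            pts.append(o[i] + R[i] @ np.asarray(pt, dtype=float))
        return float(sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])))

    # -- structure helpers ---------------------------------------------------

    def coords_between(self, seg_a: str, seg_b: str) -> set[int]:
        """Coordinate indices on the chain connecting two segments."""
        def chain(seg: str) -> list[int]:
            ids = []
            i = self.segment_body[seg]
            while i >= 0:
                ids.append(i)
                i = self.bodies[i].parent
            return ids

        ca, cb = chain(seg_a), chain(seg_b)
        shared = set(ca) & set(cb)
        out = set()
        for i in set(ca) ^ set(cb):
            qi = self.bodies[i].q_index
            if qi is not None:
                out.add(qi)
        # bodies above the common ancestor are in both chains and cancel
        return out

    def muscle_spanned_coords(self, muscle_name: str) -> set[int]:
        """Coordinates a muscle's path can depend on (structural, exact)."""
        m = next(mm for mm in self.model.muscles if mm.name == muscle_name)
        spanned: set[int] = set()
        for (sa, _), (sb, _) in zip(m.path, m.path[1:]):
            spanned |= self.coords_between(sa, sb)
        return spanned


def compile_model(model: ModelDef) -> CompiledModel:
    return CompiledModel(model)
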