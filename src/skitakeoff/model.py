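"""Rigid-body musculoskeletal model definition, validation and scaling.

A model is a tree of segments connected by joints, actuated by muscles whose
paths are straight lines through via points fixed to segments.  The base
segment attaches to the ground through a single six-degree-of-freedom free
joint; every other joint is a ball, a pin or locked.  The table coordinate
frame is right-handed with x pointing down the in-run and y perpendicular to
the table surface; gravity defaults to (0, -9.81, 0) in that frame.

Angles are radians internally; files store degrees (and metres).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Segment",
    "JointDef",
    "Muscle",
    "ModelDef",
    "ModelValidationError",
    "load_model",
    "save_model",
    "scale_model",
    "JOINT_TYPES",
    "toy_model_path",
]

JOINT_TYPES = ("free6dof", "ball", "pin", "locked")

#: number of generalized coordinates contributed by each joint type
_JOINT_DOF = {"free6dof": 6, "ball": 3, "pin": 1, "locked": 0}

_DATA_DIR = Path(__file__).parent / "data"


class ModelValidationError(ValueError):
    """A model definition violates the schema or a structural invariant."""


@dataclass
class Segment:
    """A rigid body: inertial properties plus attached markers and stations."""

    name: str
    mass: float  # kg
    com_offset: np.ndarray  # m, in the segment frame
    inertia: np.ndarray  # kg m^2, 3x3 about the COM, segment frame
    length: float = 0.0  # m, characteristic length (used for scaling checks)
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    stations: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mass <= 0:
            raise ModelValidationError(f"segment {self.name!r}: mass must be > 0")
        if self.length < 0:
            raise ModelValidationError(f"segment {self.name!r}: length must be >= 0")
        I = np.asarray(self.inertia, dtype=float)
        if I.shape != (3, 3):
            raise ModelValidationError(f"segment {self.name!r}: inertia must be 3x3")
        if not np.allclose(I, I.T, atol=1e-12):
            raise ModelValidationError(f"segment {self.name!r}: inertia not symmetric")
        if np.linalg.eigvalsh(I).min() < -1e-12:
            raise ModelValidationError(
                f"segment {self.name!r}: inertia not positive semi-definite"
            )


@dataclass
class JointDef:
    """A joint connecting a parent segment (or the ground) to a child segment."""

    name: str
    parent: str  # segment name or "ground"
    child: str
    type: str  # one of JOINT_TYPES
    location_in_parent: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray | None = None  # pin only, in the parent frame
    coordinates: list[str] = field(default_factory=list)
    ranges: list[tuple[float, float]] = field(default_factory=list)  # rad (or m)

    @property
    def locked(self) -> bool:
        return self.type == "locked"

    @property
    def n_dof(self) -> int:
        return _JOINT_DOF[self.type]

    def validate(self) -> None:
        if self.type not in JOINT_TYPES:
            raise ModelValidationError(
                f"joint {self.name!r}: unknown type {self.type!r}"
            )
        if self.type == "pin":
            if self.axis is None:
                raise ModelValidationError(f"joint {self.name!r}: pin needs an axis")
            a = np.asarray(self.axis, dtype=float)
            if np.linalg.norm(a) < 1e-12:
                raise ModelValidationError(f"joint {self.name!r}: zero-length axis")
        if self.coordinates and len(self.coordinates) != self.n_dof:
            raise ModelValidationError(
                f"joint {self.name!r}: expected {self.n_dof} coordinate names, "
                f"got {len(self.coordinates)}"
            )
        if self.ranges and len(self.ranges) != self.n_dof:
            raise ModelValidationError(
                f"joint {self.name!r}: expected {self.n_dof} ranges"
            )

    def coordinate_names(self) -> list[str]:
        if self.coordinates:
            return list(self.coordinates)
        if self.type == "free6dof":
            suffixes = ["tx", "ty", "tz", "rx", "ry", "rz"]
        elif self.type == "ball":
            suffixes = ["rx", "ry", "rz"]
        elif self.type == "pin":
            suffixes = ["angle"]
        else:
            return []
        return [f"{self.name}_{s}" for s in suffixes]


@dataclass
class Muscle:
    """A muscle-tendon actuator with a straight-line via-point path."""

    name: str
    path: list[tuple[str, np.ndarray]]  # (segment, point in segment frame)
    max_isometric_force: float  # N
    optimal_fiber_length: float = 0.1  # m
    max_contraction_velocity: float = 10.0  # optimal fiber lengths / s

    def validate(self, segment_names: set[str]) -> None:
        if self.max_isometric_force <= 0:
            raise ModelValidationError(
                f"muscle {self.name!r}: max_isometric_force must be > 0"
            )
        if len(self.path) < 2:
            raise ModelValidationError(f"muscle {self.name!r}: path needs >= 2 points")
        segs = {seg for seg, _ in self.path}
        if len(segs) < 2:
            raise ModelValidationError(
                f"muscle {self.name!r}: path must touch >= 2 distinct segments"
            )
        for seg, _ in self.path:
            if seg not in segment_names:
                raise ModelValidationError(
                    f"muscle {self.name!r}: unknown segment {seg!r} in path"
                )


@dataclass
class ModelDef:
    """A complete musculoskeletal model."""

    segments: list[Segment]
    joints: list[JointDef]
    muscles: list[Muscle] = field(default_factory=list)
    generic_height: float = 1.70  # m
    generic_mass: float = 62.0  # kg
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, -9.81, 0.0]))
    name: str = "model"

    # -- introspection -----------------------------------------------------

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments))

    @property
    def coordinate_names(self) -> list[str]:
        """Generalized coordinate names in document order (locked joints: none)."""
        names: list[str] = []
        for j in self.joints:
            names.extend(j.coordinate_names())
        return names

    @property
    def n_coordinates(self) -> int:
        return len(self.coordinate_names)

    def coordinate_ranges(self) -> dict[str, tuple[float, float]]:
        out = {}
        for j in self.joints:
            if j.ranges:
                for cname, rng in zip(j.coordinate_names(), j.ranges):
                    out[cname] = tuple(rng)
        return out

    def marker_map(self) -> dict[str, tuple[str, np.ndarray]]:
        """marker name -> (segment name, offset in segment frame)."""
        out: dict[str, tuple[str, np.ndarray]] = {}
        for s in self.segments:
            for mname, off in s.markers.items():
                out[mname] = (s.name, np.asarray(off, dtype=float))
        return out

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate segment names")
        seg_set = set(names)
        for s in self.segments:
            s.validate()
        for j in self.joints:
            j.validate()
            if j.child not in seg_set:
                raise ModelValidationError(
                    f"joint {j.name!r}: unknown child segment {j.child!r}"
                )
            if j.parent != "ground" and j.parent not in seg_set:
                raise ModelValidationError(
                    f"joint {j.name!r}: unknown parent segment {j.parent!r}"
                )
        free = [j for j in self.joints if j.type == "free6dof"]
        if len(free) != 1:
            raise ModelValidationError(
                f"model must have exactly one free6dof base joint, found {len(free)}"
            )
        if free[0].parent != "ground":
            raise ModelValidationError("the free6dof joint must attach to the ground")
        # the joint graph must be a tree rooted at the ground: every segment is
        # the child of exactly one joint, and parents reach the ground
        children = [j.child for j in self.joints]
        if len(set(children)) != len(children):
            raise ModelValidationError("a segment is the child of two joints")
        if set(children) != seg_set:
            orphans = seg_set - set(children)
            raise ModelValidationError(f"segments not attached by any joint: {orphans}")
        parent_of = {j.child: j.parent for j in self.joints}
        for s in names:
            seen = set()
            cur = s
            while cur != "ground":
                if cur in seen:
                    raise ModelValidationError(f"joint graph has a cycle at {cur!r}")
                seen.add(cur)
                cur = parent_of[cur]
        for m in self.muscles:
            m.validate(seg_set)
        dup = [m.name for m in self.muscles]
        if len(set(dup)) != len(dup):
            raise ModelValidationError("duplicate muscle names")

    def copy(self) -> "ModelDef":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# serialization (schema_version 1; degrees in files, radians in memory)
# ---------------------------------------------------------------------------


def _vec(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _seg_from_dict(d: dict) -> Segment:
    try:
        inertia = d.get("inertia", [0.0, 0.0, 0.0])
        I = np.asarray(inertia, dtype=float)
        if I.ndim == 1:  # principal moments shorthand
            I = np.diag(I)
        return Segment(
            name=d["name"],
            mass=float(d["mass"]),
            com_offset=_vec(d.get("com_offset", [0, 0, 0])),
            inertia=I,
            length=float(d.get("length", 0.0)),
            markers={k: _vec(v) for k, v in (d.get("markers") or {}).items()},
            stations={k: _vec(v) for k, v in (d.get("stations") or {}).items()},
        )
    except KeyError as e:  # pragma: no cover - error path
        raise ModelValidationError(f"segment entry missing field {e}") from e


def _joint_from_dict(d: dict) -> JointDef:
    try:
        jtype = d["type"]
        ranges = [(lo, hi) for lo, hi in d.get("ranges") or []]
        j = JointDef(
            name=d["name"],
            parent=d["parent"],
            child=d["child"],
            type=jtype,
            location_in_parent=_vec(d.get("location_in_parent", [0, 0, 0])),
            axis=_vec(d["axis"]) if d.get("axis") is not None else None,
            coordinates=list(d.get("coordinates") or []),
            ranges=[],
        )
        # file ranges are degrees for rotational coordinates, metres otherwise
        if ranges:
            conv = []
            cnames = j.coordinate_names()
            for cname, (lo, hi) in zip(cnames, ranges):
                if _is_rotational_name(jtype, cname, cnames):
                    conv.append((np.deg2rad(lo), np.deg2rad(hi)))
                else:
                    conv.append((float(lo), float(hi)))
            j.ranges = conv
        return j
    except KeyError as e:  # pragma: no cover - error path
        raise ModelValidationError(f"joint entry missing field {e}") from e


def _is_rotational_name(jtype: str, cname: str, cnames: list[str]) -> bool:
    if jtype in ("pin", "ball"):
        return True
    if jtype == "free6dof":
        return cnames.index(cname) >= 3
    return False


def rotational_mask(model: ModelDef) -> list[bool]:
    """Per-coordinate flag: True if the coordinate is an angle (rad)."""
    mask: list[bool] = []
    for j in model.joints:
        cnames = j.coordinate_names()
        mask.extend(_is_rotational_name(j.type, c, cnames) for c in cnames)
    return mask


def _muscle_from_dict(d: dict) -> Muscle:
    try:
        return Muscle(
            name=d["name"],
            path=[(seg, _vec(pt)) for seg, pt in d["path"]],
            max_isometric_force=float(d["max_isometric_force"]),
            optimal_fiber_length=float(d.get("optimal_fiber_length", 0.1)),
            max_contraction_velocity=float(d.get("max_contraction_velocity", 10.0)),
        )
    except KeyError as e:  # pragma: no cover - error path
        raise ModelValidationError(f"muscle entry missing field {e}") from e


def model_from_dict(data: dict) -> ModelDef:
    if int(data.get("schema_version", 1)) != 1:
        raise ModelValidationError(
            f"unsupported schema_version {data.get('schema_version')!r}"
        )
    model = ModelDef(
        segments=[_seg_from_dict(s) for s in data.get("segments", [])],
        joints=[_joint_from_dict(j) for j in data.get("joints", [])],
        muscles=[_muscle_from_dict(m) for m in data.get("muscles", [])],
        generic_height=float(data.get("generic_height", 1.70)),
        generic_mass=float(data.get("generic_mass", 62.0)),
        gravity=_vec(data.get("gravity", [0.0, -9.81, 0.0])),
        name=data.get("name", "model"),
    )
    model.validate()
    return model


def model_to_dict(model: ModelDef) -> dict:
    def lst(a):
        return np.asarray(a, dtype=float).tolist()

    joints = []
    for j in model.joints:
        d = {
            "name": j.name,
            "parent": j.parent,
            "child": j.child,
            "type": j.type,
            "location_in_parent": lst(j.location_in_parent),
        }
        if j.axis is not None:
            d["axis"] = lst(j.axis)
        if j.coordinates:
            d["coordinates"] = list(j.coordinates)
        if j.ranges:
            cnames = j.coordinate_names()
            out = []
            for cname, (lo, hi) in zip(cnames, j.ranges):
                if _is_rotational_name(j.type, cname, cnames):
                    out.append([float(np.rad2deg(lo)), float(np.rad2deg(hi))])
                else:
                    out.append([float(lo), float(hi)])
            d["ranges"] = out
        joints.append(d)
    return {
        "schema_version": 1,
        "name": model.name,
        "generic_height": model.generic_height,
        "generic_mass": model.generic_mass,
        "gravity": lst(model.gravity),
        "joints": joints,
        "segments": [
            {
                "name": s.name,
                "mass": s.mass,
                "com_offset": lst(s.com_offset),
                "inertia": lst(s.inertia),
                "length": s.length,
                "markers": {k: lst(v) for k, v in s.markers.items()},
                "stations": {k: lst(v) for k, v in s.stations.items()},
            }
            for s in model.segments
        ],
        "muscles": [
            {
                "name": m.name,
                "path": [[seg, lst(pt)] for seg, pt in m.path],
                "max_isometric_force": m.max_isometric_force,
                "optimal_fiber_length": m.optimal_fiber_length,
                "max_contraction_velocity": m.max_contraction_velocity,
            }
            for m in model.muscles
        ],
    }


def load_model(path: str | Path) -> ModelDef:
    """Load and validate a model from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ModelValidationError(f"{path}: not a mapping at top level")
    return model_from_dict(data)


def save_model(model: ModelDef, path: str | Path) -> None:
    path = Path(path)
    data = model_to_dict(model)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def toy_model_path(which: str = "toy9") -> Path:
    """Path of a bundled model ("toy9": 3-D 9-segment; "planar4": sagittal)."""
    p = _DATA_DIR / f"{which}.yaml"
    if not p.exists():
        raise FileNotFoundError(p)
    return p


# ---------------------------------------------------------------------------
# subject scaling
# ---------------------------------------------------------------------------


def scale_model(
    model: ModelDef,
    height: float,
    mass: float,
    strength_doubling: bool = False,
    strength_scale: float | None = None,
) -> ModelDef:
    """Scale a generic model to a subject's height and mass.

    Lengths (and all attached points) scale by ``height / generic_height``;
    segment masses scale uniformly so the total equals ``mass``; inertias
    scale by (mass ratio) x (length ratio)^2.  Maximum isometric forces are
    multiplied by 2 when ``strength_doubling`` is set and then by the strength
    scaling factor ``s = (mass * height) / (generic_mass * generic_height)``
    (muscle-volume proportionality), unless ``strength_scale`` overrides s.
    """
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    lam = height / model.generic_height
    mu = mass / model.generic_mass
    s = strength_scale if strength_scale is not None else mu * lam
    d = 2.0 if strength_doubling else 1.0

    out = model.copy()
    for seg in out.segments:
        seg.mass *= mu
        seg.length *= lam
        seg.com_offset = np.asarray(seg.com_offset) * lam
        seg.inertia = np.asarray(seg.inertia) * (mu * lam**2)
        seg.markers = {k: np.asarray(v) * lam for k, v in seg.markers.items()}
        seg.stations = {k: np.asarray(v) * lam for k, v in seg.stations.items()}
    for j in out.joints:
        j.location_in_parent = np.asarray(j.location_in_parent) * lam
    for m in out.muscles:
        m.path = [(seg, np.asarray(pt) * lam) for seg, pt in m.path]
        m.optimal_fiber_length *= lam
        m.max_isometric_force *= d * s
    out.generic_height = height
    out.generic_mass = mass
    out.validate()
    return out
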