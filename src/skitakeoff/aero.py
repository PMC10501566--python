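"""Posture-indexed aerodynamic database: grid, interpolation, scaling, loads.

The database stores per-part aerodynamic forces and moments (10 body parts:
left/right calves, thighs, forearms, upper arms, plus trunk and head) indexed
by the seven posture angles, at reference conditions (jumper height 1.70 m,
flow speed 23 m/s, air density rho_ref).  The reference grid is organised in
blocks keyed by knee angle δ2 — three take-off blocks (θ2 = θ1 = δ4 = α = 0)
and two early-flight blocks — totalling 278 postures.

Queries are answered by multilinear interpolation inside a δ2 block followed
by linear blending between the two bracketing δ2 levels; out-of-range
coordinates are clamped to the block boundary with a warning.  Forces scale
with air density, linearly with body height (cross-sectional area) and
quadratically with speed: ``F = (rho/rho_ref) (h/1.70) (w/23)^2 F_ref``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import ExternalLoad
from .kinematics import MotionTrajectory, PostureAngles, extract_posture_angles
from .model import ModelDef
from .tree import CompiledModel

__all__ = [
    "ANGLE_ORDER",
    "PART_NAMES",
    "REF_HEIGHT",
    "REF_SPEED",
    "REF_RHO",
    "GridBlock",
    "AeroRecord",
    "AeroDatabase",
    "AeroLoads",
    "grid_blocks",
    "build_reference_grid",
    "scale_aero",
    "apply_aero_loads",
    "DEFAULT_PART_MAP",
]

#: within-block interpolation axes, in enumeration order
ANGLE_ORDER = ("delta3", "theta2", "theta1", "delta4", "delta1", "alpha")

PART_NAMES = (
    "trunk", "head",
    "upperarm_l", "upperarm_r", "forearm_l", "forearm_r",
    "thigh_l", "thigh_r", "calf_l", "calf_r",
)

REF_HEIGHT = 1.70  # m
REF_SPEED = 23.0  # m/s
REF_RHO = 1.225  # kg/m^3


@dataclass(frozen=True)
class GridBlock:
    """One δ2 level of the reference grid with its axis values (degrees)."""

    phase: str  # "takeoff" | "early_flight"
    delta2: float
    axes: dict[str, tuple[float, ...]]  # keyed by ANGLE_ORDER entries

    @property
    def n_postures(self) -> int:
        return int(np.prod([len(v) for v in self.axes.values()]))

    def postures(self) -> list[PostureAngles]:
        """Cartesian product, lexicographic in ANGLE_ORDER."""
        combos = itertools.product(*(self.axes[a] for a in ANGLE_ORDER))
        return [
            PostureAngles(
                delta1=c[4], delta2=self.delta2, delta3=c[0], delta4=c[3],
                theta1=c[2], theta2=c[1], alpha=c[5],
            )
            for c in combos
        ]


def _block(phase, d2, d3, t2=(0.0,), t1=(0.0,), d4=(0.0,), d1=(30.0, 90.0),
           al=(0.0,)) -> GridBlock:
    return GridBlock(phase, float(d2), {
        "delta3": tuple(d3), "theta2": tuple(t2), "theta1": tuple(t1),
        "delta4": tuple(d4), "delta1": tuple(d1), "alpha": tuple(al),
    })


_FLIGHT = dict(d3=(80.0, 110.0, 140.0, 180.0), t2=(0.0, 30.0),
               t1=(0.0, 45.0), d4=(0.0, 30.0), al=(0.0, 30.0))

#: the reference posture grid: 8 + 10 + 4 + 128 + 128 = 278 postures
REFERENCE_BLOCKS: tuple[GridBlock, ...] = (
    _block("takeoff", 90, (20.0, 50.0, 80.0, 110.0)),
    _block("takeoff", 120, (20.0, 50.0, 80.0, 110.0, 140.0)),
    _block("takeoff", 150, (20.0, 50.0)),
    _block("early_flight", 150, **_FLIGHT),
    _block("early_flight", 180, **_FLIGHT),
)


def grid_blocks() -> tuple[GridBlock, ...]:
    return REFERENCE_BLOCKS


def build_reference_grid() -> list[PostureAngles]:
    """All postures of the reference grid, block order then lexicographic."""
    out: list[PostureAngles] = []
    for b in REFERENCE_BLOCKS:
        out.extend(b.postures())
    return out


# ---------------------------------------------------------------------------
# records and database
# ---------------------------------------------------------------------------


@dataclass
class AeroRecord:
    """Aerodynamic forces/moments for one posture at reference conditions."""

    posture: PostureAngles
    forces: dict[str, np.ndarray]  # part -> (3,) N
    moments: dict[str, np.ndarray] = field(default_factory=dict)  # part -> (3,) N m
    ref_height: float = REF_HEIGHT
    ref_speed: float = REF_SPEED
    ref_rho: float = REF_RHO
    phase: str = "takeoff"

    def __post_init__(self):
        if set(self.forces) != set(PART_NAMES):
            raise ValueError(
                f"record must carry exactly the {len(PART_NAMES)} parts"
            )
        self.forces = {k: np.asarray(v, dtype=float) for k, v in self.forces.items()}
        if not self.moments:
            self.moments = {k: np.zeros(3) for k in PART_NAMES}
        self.moments = {k: np.asarray(v, dtype=float) for k, v in self.moments.items()}

    @property
    def total_force(self) -> np.ndarray:
        return np.sum([self.forces[p] for p in PART_NAMES], axis=0)

    @property
    def total_moment(self) -> np.ndarray:
        return np.sum([self.moments[p] for p in PART_NAMES], axis=0)

    def as_array(self) -> np.ndarray:
        """(10, 6) array: per part [Fx Fy Fz Mx My Mz], PART_NAMES order."""
        return np.array(
            [np.concatenate([self.forces[p], self.moments[p]]) for p in PART_NAMES]
        )

    @classmethod
    def from_array(cls, posture: PostureAngles, arr: np.ndarray,
                   phase: str = "takeoff", **refs) -> "AeroRecord":
        arr = np.asarray(arr, dtype=float).reshape(len(PART_NAMES), 6)
        return cls(
            posture=posture,
            forces={p: arr[i, :3] for i, p in enumerate(PART_NAMES)},
            moments={p: arr[i, 3:] for i, p in enumerate(PART_NAMES)},
            phase=phase, **refs,
        )


def _posture_key(p: PostureAngles) -> tuple:
    return (p.delta2, p.delta3, p.theta2, p.theta1, p.delta4, p.delta1, p.alpha)


class AeroDatabase:
    """Blocks of gridded per-part aerodynamic records with interpolation."""

    def __init__(
        self,
        blocks: list[tuple[GridBlock, np.ndarray]],
        ref_height: float = REF_HEIGHT,
        ref_speed: float = REF_SPEED,
        ref_rho: float = REF_RHO,
        provenance: str = "",
    ):
        if not blocks:
            raise ValueError("empty aerodynamic database")
        self.blocks = []
        for gb, data in blocks:
            shape = tuple(len(gb.axes[a]) for a in ANGLE_ORDER) + (len(PART_NAMES), 6)
            data = np.asarray(data, dtype=float).reshape(shape)
            self.blocks.append((gb, data))
        self.ref_height = float(ref_height)
        self.ref_speed = float(ref_speed)
        self.ref_rho = float(ref_rho)
        self.provenance = provenance
        self._check_duplicates()

    # -- construction ------------------------------------------------------

    def _check_duplicates(self):
        seen = set()
        for gb, _ in self.blocks:
            for p in gb.postures():
                k = _posture_key(p)
                if k in seen:
                    raise ValueError(f"duplicate posture in database: {k}")
                seen.add(k)

    @classmethod
    def from_records(
        cls, records: list[AeroRecord], provenance: str = "", **refs
    ) -> "AeroDatabase":
        """Assemble a database from records; each (phase, δ2) group must be a
        full Cartesian product of its axis values."""
        if not records:
            raise ValueError("empty aerodynamic database")
        groups: dict[tuple[str, float], list[AeroRecord]] = {}
        for r in records:
            groups.setdefault((r.phase, r.posture.delta2), []).append(r)
        blocks = []
        for (phase, d2), recs in groups.items():
            axes = {
                a: tuple(sorted({getattr(r.posture, a) for r in recs}))
                for a in ANGLE_ORDER
            }
            gb = GridBlock(phase, d2, axes)
            if gb.n_postures != len(recs):
                raise ValueError(
                    f"block (phase={phase}, delta2={d2}) is not a full "
                    f"Cartesian product: {len(recs)} records, grid needs "
                    f"{gb.n_postures}"
                )
            shape = tuple(len(axes[a]) for a in ANGLE_ORDER)
            data = np.full(shape + (len(PART_NAMES), 6), np.nan)
            for r in recs:
                idx = tuple(
                    axes[a].index(getattr(r.posture, a)) for a in ANGLE_ORDER
                )
                if np.isfinite(data[idx]).any():
                    raise ValueError(f"duplicate posture {_posture_key(r.posture)}")
                data[idx] = r.as_array()
            blocks.append((gb, data))
        first = records[0]
        refs.setdefault("ref_height", first.ref_height)
        refs.setdefault("ref_speed", first.ref_speed)
        refs.setdefault("ref_rho", first.ref_rho)
        return cls(blocks, provenance=provenance, **refs)

    # -- introspection -----------------------------------------------------

    @property
    def n_records(self) -> int:
        return sum(gb.n_postures for gb, _ in self.blocks)

    def records(self) -> list[AeroRecord]:
        out = []
        for gb, data in self.blocks:
            flat = data.reshape(-1, len(PART_NAMES), 6)
            for p, arr in zip(gb.postures(), flat):
                out.append(
                    AeroRecord.from_array(
                        p, arr, phase=gb.phase, ref_height=self.ref_height,
                        ref_speed=self.ref_speed, ref_rho=self.ref_rho,
                    )
                )
        return out

    # -- interpolation -----------------------------------------------------

    def _eval_block(self, gb: GridBlock, data: np.ndarray,
                    query: PostureAngles) -> tuple[np.ndarray, float]:
        """Multilinear interpolation in one block; returns (value, clamp)."""
        arr = data
        clamp = 0.0
        for a in ANGLE_ORDER:
            vals = gb.axes[a]
            x = float(getattr(query, a))
            if len(vals) == 1:
                arr = arr[0]
                clamp += abs(x - vals[0])
                continue
            if x <= vals[0]:
                clamp += vals[0] - x
                arr = arr[0]
            elif x >= vals[-1]:
                clamp += x - vals[-1]
                arr = arr[-1]
            else:
                j = int(np.searchsorted(vals, x, side="right")) - 1
                if vals[j] == x:
                    arr = arr[j]  # exact node: no arithmetic, stays bitwise
                else:
                    t = (x - vals[j]) / (vals[j + 1] - vals[j])
                    arr = (1.0 - t) * arr[j] + t * arr[j + 1]
        return arr, clamp

    def _eval_level(self, d2: float, query: PostureAngles) -> np.ndarray:
        cands = [(gb, data) for gb, data in self.blocks if gb.delta2 == d2]
        results = [self._eval_block(gb, data, query) for gb, data in cands]
        # several blocks can share a δ2 level (take-off vs early flight at
        # 150°): pick the one requiring the least clamping of the query
        best = min(range(len(results)), key=lambda i: results[i][1])
        return results[best][0]

    def interpolate(self, query: PostureAngles) -> AeroRecord:
        """Per-part forces/moments at an arbitrary posture.

        Multilinear inside the bracketing δ2 blocks, linear blend across δ2;
        coordinates outside the grid are clamped to the boundary.
        """
        vals = [getattr(query, a) for a in ANGLE_ORDER] + [query.delta2]
        if not all(np.isfinite(vals)):
            raise ValueError("query posture must be finite")
        levels = sorted({gb.delta2 for gb, _ in self.blocks})
        d2 = float(query.delta2)
        if d2 < levels[0] or d2 > levels[-1]:
            warnings.warn(
                f"query delta2={d2} outside grid [{levels[0]}, {levels[-1]}]; "
                "clamped"
            )
            d2 = float(np.clip(d2, levels[0], levels[-1]))
        j = int(np.searchsorted(levels, d2, side="right")) - 1
        j = min(j, len(levels) - 1)
        if levels[j] == d2 or len(levels) == 1:
            arr = self._eval_level(levels[j], query)
        else:
            t = (d2 - levels[j]) / (levels[j + 1] - levels[j])
            arr = (1.0 - t) * self._eval_level(levels[j], query) \
                + t * self._eval_level(levels[j + 1], query)
        return AeroRecord.from_array(
            query, arr, ref_height=self.ref_height, ref_speed=self.ref_speed,
            ref_rho=self.ref_rho,
        )


def interpolate(db: AeroDatabase, query: PostureAngles) -> AeroRecord:
    """Functional alias of :meth:`AeroDatabase.interpolate`."""
    return db.interpolate(query)


# ---------------------------------------------------------------------------
# scaling (height linear, speed quadratic, density ratio)
# ---------------------------------------------------------------------------


def scale_aero(
    record: AeroRecord,
    height: float,
    speed: float,
    rho: float | None = None,
) -> AeroRecord:
    """Scale a record from reference conditions to a subject and speed."""
    if height < 0 or speed < 0:
        raise ValueError("height and speed must be non-negative")
    rho = record.ref_rho if rho is None else rho
    if rho <= 0:
        raise ValueError("air density must be positive")
    k = (rho / record.ref_rho) * (height / record.ref_height) \
        * (speed / record.ref_speed) ** 2
    return AeroRecord(
        posture=record.posture,
        forces={p: record.forces[p] * k for p in PART_NAMES},
        moments={p: record.moments[p] * k for p in PART_NAMES},
        ref_height=record.ref_height,
        ref_speed=record.ref_speed,
        ref_rho=record.ref_rho,
        phase=record.phase,
    )


# ---------------------------------------------------------------------------
# mapping per-part forces onto model segments
# ---------------------------------------------------------------------------

#: part -> segment for the bundled 9-segment model (arms fold into the
#: head+arms lump; calf-and-ski forces land on the shanks)
DEFAULT_PART_MAP = {
    "trunk": "torso",
    "head": "headarms",
    "upperarm_l": "headarms", "upperarm_r": "headarms",
    "forearm_l": "headarms", "forearm_r": "headarms",
    "thigh_l": "thigh_l", "thigh_r": "thigh_r",
    "calf_l": "shank_l", "calf_r": "shank_r",
}


@dataclass
class AeroLoads:
    """Per-part external loads plus whole-body diagnostics."""

    loads: list[ExternalLoad]
    whole_body_force: np.ndarray  # (n, 3), scaled
    speeds: np.ndarray  # (n,)
    postures: list[PostureAngles]


def apply_aero_loads(
    model: ModelDef,
    motion: MotionTrajectory,
    db: AeroDatabase,
    speed: float | np.ndarray | None = None,
    rho: float | None = None,
    height: float | None = None,
    part_map: dict[str, str] | None = None,
    apply_moments: bool = False,
    postures: list[PostureAngles] | None = None,
) -> AeroLoads:
    """Aerodynamic external loads along a motion.

    Posture angles are extracted per frame (or supplied), the database is
    interpolated and scaled, and each mapped part's force is applied at its
    segment's centre of mass in the ground frame.  ``speed`` defaults to the
    whole-body COM speed per frame; a scalar (e.g. the approach speed) may be
    given instead.
    """
    comp = CompiledModel(model)
    part_map = DEFAULT_PART_MAP if part_map is None else part_map
    height = model.generic_height if height is None else height
    n = motion.n_frames
    if postures is None:
        postures = extract_posture_angles(model, motion)
    if speed is None:
        com = np.array([comp.com_position(motion.q[f]) for f in range(n)])
        speeds = np.linalg.norm(np.gradient(com, motion.times, axis=0), axis=1)
    else:
        speeds = np.broadcast_to(np.asarray(speed, dtype=float), (n,)).copy()

    part_force = {p: np.zeros((n, 3)) for p in PART_NAMES}
    part_moment = {p: np.zeros((n, 3)) for p in PART_NAMES}
    whole = np.zeros((n, 3))
    for f in range(n):
        rec = scale_aero(db.interpolate(postures[f]), height, speeds[f], rho)
        for p in PART_NAMES:
            part_force[p][f] = rec.forces[p]
            part_moment[p][f] = rec.moments[p]
        whole[f] = rec.total_force

    loads: list[ExternalLoad] = []
    for p in PART_NAMES:
        if p not in part_map or part_map[p] is None:
            if np.any(part_force[p] != 0) or (
                apply_moments and np.any(part_moment[p] != 0)
            ):
                raise ValueError(
                    f"aerodynamic part {p!r} carries force but maps to no segment"
                )
            continue
        seg = model.segment(part_map[p])
        loads.append(
            ExternalLoad(
                segment=seg.name,
                force=part_force[p],
                point=np.tile(np.asarray(seg.com_offset, dtype=float), (n, 1)),
                torque=part_moment[p] if apply_moments else np.zeros((n, 3)),
                point_frame="segment",
                name=f"aero_{p}",
            )
        )
    return AeroLoads(loads=loads, whole_body_force=whole, speeds=speeds,
                     postures=postures)
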