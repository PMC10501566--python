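"""Static optimization of muscle activations and torque contributions.

Muscle redundancy is resolved per frame by minimizing the sum of squared
activations subject to reproducing the inverse-dynamics joint torques:

    min  sum_i a_i^2 + w_res sum_j rho_j^2
    s.t. sum_i a_i F_i^max f_l f_v r_ij + rho_j T_res = tau_j   for all j
         0 <= a_i <= 1

Reserve actuators (rho, heavily penalized) guarantee feasibility and expose
modeling gaps.  Moment arms follow the tendon-excursion definition
``r_ij = -dL_i/dq_j`` (central differences on the straight-line via-point
path length).  Frames are independent: no activation dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._qp import solve_diag_qp
from .dynamics import GeneralizedForces
from .kinematics import MotionTrajectory
from .model import ModelDef
from .tree import CompiledModel

__all__ = [
    "MuscleSolution",
    "moment_arms",
    "static_optimization",
    "torque_contributions",
    "force_length",
    "force_velocity",
    "DEFAULT_GROUPS",
]

#: extensor groupings used in summary reports (bundled toy-model muscles)
DEFAULT_GROUPS = {
    "ankle_plantarflexors": ["soleus_l", "soleus_r", "gasmed_l", "gasmed_r"],
    "knee_extensors": ["vaslat_l", "vaslat_r", "recfem_l", "recfem_r"],
    "hip_extensors": ["glmax_l", "glmax_r", "bflh_l", "bflh_r",
                      "semimem_l", "semimem_r"],
}


def force_length(l_norm: np.ndarray, gamma: float = 0.45) -> np.ndarray:
    """Active force-length multiplier: Gaussian around the optimal length."""
    return np.exp(-((np.asarray(l_norm) - 1.0) ** 2) / gamma)


def force_velocity(v_norm: np.ndarray) -> np.ndarray:
    """Hill-type force-velocity multiplier.

    ``v_norm`` is the lengthening rate in optimal fiber lengths per second
    divided by the maximum contraction velocity (positive = lengthening).
    Concentric force falls hyperbolically to zero at full shortening speed;
    eccentric force is capped at 1.4.
    """
    s = -np.asarray(v_norm, dtype=float)  # shortening rate
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (1.0 - s) / (1.0 + s / 0.25)
    f = np.where(s >= 1.0, 0.0, f)
    f = np.where(s <= -0.25 * 0.9, 1.4, f)  # near the eccentric asymptote
    return np.clip(f, 0.0, 1.4)


@dataclass
class MuscleSolution:
    """Per-frame activations, forces, moment arms, reserves and diagnostics."""

    muscle_names: list[str]
    coordinate_names: list[str]  # actuated coordinates only
    times: np.ndarray
    activations: np.ndarray  # (n, nm) in [0, 1]
    forces: np.ndarray  # (n, nm) N
    moment_arms: np.ndarray  # (n, nm, nc) m
    reserves: np.ndarray  # (n, nc) N m
    objective: np.ndarray  # (n,)
    kkt_residual: np.ndarray  # (n,)
    path_lengths: np.ndarray | None = None  # (n, nm) m
    lengthening_velocities: np.ndarray | None = None  # (n, nm) m/s
    metadata: dict = field(default_factory=dict)

    def muscle(self, name: str) -> int:
        return self.muscle_names.index(name)


# ---------------------------------------------------------------------------
# moment arms
# ---------------------------------------------------------------------------


def moment_arms(
    model: ModelDef | CompiledModel,
    q: np.ndarray,
    muscles: list[str] | None = None,
    coords: list[int] | None = None,
    step: float = 1e-6,
) -> np.ndarray:
    """Tendon-excursion moment arm matrix r_ij = -dL_i/dq_j at pose q.

    Coordinates a muscle cannot structurally span are exactly zero (no
    numerical noise).  A degenerate path (coincident consecutive via points)
    yields NaN for that muscle with a warning.
    """
    comp = model if isinstance(model, CompiledModel) else CompiledModel(model)
    q = np.asarray(q, dtype=float)
    names = muscles if muscles is not None else [m.name for m in comp.model.muscles]
    cidx = coords if coords is not None else list(range(comp.nq))
    R = np.zeros((len(names), len(cidx)))
    fk0 = comp.fk(q)
    for i, name in enumerate(names):
        m = next(mm for mm in comp.model.muscles if mm.name == name)
        pts = [comp.world_point(q, seg, pt, fk=fk0) for seg, pt in m.path]
        if any(np.linalg.norm(b - a) < 1e-12 for a, b in zip(pts, pts[1:])):
            warnings.warn(f"muscle {name!r}: degenerate path (coincident points)")
            R[i, :] = np.nan
            continue
        spanned = comp.muscle_spanned_coords(name)
        for jj, j in enumerate(cidx):
            if j not in spanned:
                continue
            qp = q.copy(); qp[j] += step
            qm = q.copy(); qm[j] -= step
            R[i, jj] = -(comp.path_length(qp, name) - comp.path_length(qm, name)) \
                / (2.0 * step)
    return R


def _actuated_coords(comp: CompiledModel) -> list[int]:
    spanned: set[int] = set()
    for m in comp.model.muscles:
        spanned |= comp.muscle_spanned_coords(m.name)
    return sorted(spanned)


# ---------------------------------------------------------------------------
# static optimization
# ---------------------------------------------------------------------------


def static_optimization(
    model: ModelDef,
    motion: MotionTrajectory,
    torques: GeneralizedForces,
    force_model: str = "ideal",
    w_res: float = 1000.0,
    t_res: float = 1.0,
    coords: list[str] | None = None,
) -> MuscleSolution:
    """Resolve muscle redundancy against inverse-dynamics torques.

    ``force_model``: "ideal" (F = a F_max) or "flv" (rigid-tendon
    force-length and force-velocity multipliers on the path length/velocity).
    ``coords`` restricts the constrained coordinates (default: all
    muscle-actuated ones).
    """
    if force_model not in ("ideal", "flv"):
        raise ValueError("force_model must be 'ideal' or 'flv'")
    comp = CompiledModel(model)
    if not comp.model.muscles:
        raise ValueError("model has no muscles")
    mnames = [m.name for m in comp.model.muscles]
    if coords is None:
        cidx = _actuated_coords(comp)
    else:
        cidx = [comp.coordinate_names.index(c) for c in coords]
    cnames = [comp.coordinate_names[j] for j in cidx]
    nm, nc, n = len(mnames), len(cidx), motion.n_frames

    fmax = np.array([m.max_isometric_force for m in comp.model.muscles])
    lopt = np.array([m.optimal_fiber_length for m in comp.model.muscles])
    vmax = np.array([m.max_contraction_velocity for m in comp.model.muscles])

    acts = np.empty((n, nm))
    forces = np.empty((n, nm))
    arms = np.empty((n, nm, nc))
    reserves = np.empty((n, nc))
    objective = np.empty(n)
    kkt = np.empty(n)
    plen = np.empty((n, nm))
    pvel = np.zeros((n, nm))

    d = np.concatenate([np.ones(nm), w_res * np.ones(nc)])
    lb = np.concatenate([np.zeros(nm), np.full(nc, -np.inf)])
    ub = np.concatenate([np.ones(nm), np.full(nc, np.inf)])

    for f in range(n):
        q = motion.q[f]
        R = moment_arms(comp, q, coords=cidx)
        arms[f] = R
        plen[f] = [comp.path_length(q, nme) for nme in mnames]
        scale = fmax.copy()
        if force_model == "flv":
            if motion.qdot is not None:
                # dL/dt = sum_j dL/dq_j qd_j = -sum_j r_ij qd_j
                pvel[f] = -(R @ motion.qdot[f][cidx])
            scale = scale * force_length(plen[f] / lopt) \
                * force_velocity(pvel[f] / (lopt * vmax))
        A = np.hstack([(R * scale[:, None]).T, t_res * np.eye(nc)])
        b = torques.tau[f, cidx]
        x, lam = solve_diag_qp(d, A, b, lb, ub)
        a, rho = x[:nm], x[nm:]
        acts[f] = a
        forces[f] = a * scale
        reserves[f] = rho * t_res
        objective[f] = float(a @ a + w_res * (rho @ rho))
        free = (a > 1e-9) & (a < 1.0 - 1e-9)
        stat = 2.0 * d * x + A.T @ lam
        kkt[f] = max(
            float(np.max(np.abs(stat[:nm][free]), initial=0.0)),
            float(np.max(np.abs(stat[nm:]), initial=0.0)),
            float(np.max(np.abs(A @ x - b), initial=0.0)),
        )

    big = np.nonzero(np.max(np.abs(reserves), axis=1) > 1.0)[0]
    if len(big):
        warnings.warn(
            f"reserve torques exceed 1 N·m in {len(big)} frames "
            "(model strength or torque inputs may be inconsistent)"
        )
    return MuscleSolution(
        muscle_names=mnames,
        coordinate_names=cnames,
        times=motion.times.copy(),
        activations=acts,
        forces=forces,
        moment_arms=arms,
        reserves=reserves,
        objective=objective,
        kkt_residual=kkt,
        path_lengths=plen,
        lengthening_velocities=pvel,
        metadata={"force_model": force_model, "w_res": w_res, "t_res": t_res},
    )


def torque_contributions(
    solution: MuscleSolution,
    groups: dict[str, list[str]] | None = None,
) -> dict:
    """Per-muscle joint-torque contributions tau_ij = F_i r_ij.

    Returns ``{"per_muscle": (n, nm, nc) array, "groups": {...}}`` where each
    group entry is the (n, nc) summed contribution of its member muscles.
    """
    contrib = solution.forces[:, :, None] * solution.moment_arms
    out = {"per_muscle": contrib, "coordinate_names": solution.coordinate_names,
           "muscle_names": solution.muscle_names}
    if groups is not None:
        gsum = {}
        for gname, members in groups.items():
            idx = [solution.muscle(m) for m in members if m in solution.muscle_names]
            gsum[gname] = contrib[:, idx, :].sum(axis=1)
        out["groups"] = gsum
    return out
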