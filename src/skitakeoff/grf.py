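"""Iterative inverse-dynamics estimation of the ground reaction force.

The estimator starts from all-zero GRF components applied at the proximal
second metatarsal of each foot, runs inverse dynamics, and adds half of each
pelvis residual component to the corresponding GRF component of the left and
right legs (assumed to carry equal loads).  Iteration stops when the mean RMS
of the residuals over the simulation window falls below the convergence
threshold (0.001 N for forces, 0.001 N·m for torques).

Two modes are provided: ``full12`` updates all six components per leg (the
in-lab verification setting) and ``takeoff_constrained`` the take-off
setting, where the medial-lateral force and all moments are held at zero, the
normal force Fy is iterated, and the along-table force Fx is slaved to the
friction law Fx = -mu * Fy (mu = 0.018, from a friction angle of about 1°).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    WRENCH_COMPONENTS,
    ExternalLoad,
    GeneralizedForces,
    ResidualWrench,
    inverse_dynamics,
)
from .kinematics import MotionTrajectory
from .model import ModelDef
from .tree import CompiledModel

__all__ = [
    "GRFConfig",
    "GRFState",
    "GRFResult",
    "estimate_grf",
    "mean_rms_residual",
    "compare_grf",
    "grf_external_loads",
]

MODES = ("full12", "takeoff_constrained")

#: GRF axes in the table frame and their conventional biomechanics names
AXIS_NAMES = {
    "x": "anterior_posterior",
    "y": "vertical",
    "z": "medial_lateral",
}


@dataclass
class GRFConfig:
    """Settings of the iterative estimator."""

    threshold: float = 0.001  # N (forces) / N m (torques)
    max_iterations: int = 500
    mode: str = "full12"
    mu: float | None = 0.018  # friction coefficient (take-off mode)
    friction_angle_deg: float | None = None  # alternative input: mu = tan(angle)
    friction_sign: float = -1.0  # friction opposes downhill (+x) sliding
    station: str = "proximal_metatarsal"
    divergence_patience: int = 10
    active_components: tuple[str, ...] | None = None  # override convergence set

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.friction_angle_deg is not None and self.mu is None:
            self.mu = float(np.tan(np.radians(self.friction_angle_deg)))
        if self.mu is None:
            self.mu = 0.0
        if not 0 <= self.mu < 1:
            raise ValueError("friction coefficient must satisfy 0 <= mu < 1")

    @property
    def active(self) -> tuple[str, ...]:
        if self.active_components is not None:
            return self.active_components
        if self.mode == "full12":
            return WRENCH_COMPONENTS
        # constrained mode: only Fy is updated by the residual rule; Fx is
        # slaved to the friction law and its residual cannot be annulled
        return ("Fy",)


@dataclass
class GRFState:
    """Per-leg six-component GRF trajectories at one iteration."""

    times: np.ndarray
    left: np.ndarray  # (n, 6): Fx, Fy, Fz, Mx, My, Mz
    right: np.ndarray
    iteration: int = 0

    @property
    def total_force(self) -> np.ndarray:
        return self.left[:, :3] + self.right[:, :3]

    def leg(self, side: str) -> np.ndarray:
        return self.left if side == "left" else self.right


@dataclass
class GRFResult:
    """Estimator output: final state, convergence diagnostics, torques."""

    state: GRFState
    residual_history: list[float]
    converged: bool
    iterations: int
    final_residual: ResidualWrench
    generalized_forces: GeneralizedForces
    metadata: dict = field(default_factory=dict)

    @property
    def final_mean_rms(self) -> float:
        return self.residual_history[-1]


def mean_rms_residual(
    residuals: ResidualWrench | np.ndarray,
    active: tuple[str, ...] | list[int] = WRENCH_COMPONENTS,
) -> float:
    """Mean over active components of the per-component RMS over time.

    Units are mixed (N for force components, N·m for torque components),
    matching the estimator's convergence metric.
    """
    data = residuals.data if isinstance(residuals, ResidualWrench) else residuals
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if len(active) == 0:
        raise ValueError("active component set must not be empty")
    idx = [
        WRENCH_COMPONENTS.index(c) if isinstance(c, str) else int(c)
        for c in active
    ]
    rms = np.sqrt(np.mean(data[:, idx] ** 2, axis=0))
    return float(np.mean(rms))


def grf_external_loads(
    model: ModelDef,
    state: GRFState,
    station: str = "proximal_metatarsal",
    feet: tuple[str, str] = ("foot_l", "foot_r"),
) -> list[ExternalLoad]:
    """Express a GRF state as the two per-leg external loads."""
    n = len(state.times)
    out = []
    for seg, data in zip(feet, (state.left, state.right)):
        pt = np.asarray(model.segment(seg).stations[station], dtype=float)
        out.append(
            ExternalLoad(
                segment=seg,
                force=data[:, :3],
                point=np.tile(pt, (n, 1)),
                torque=data[:, 3:],
                point_frame="segment",
                name=f"grf_{seg}",
            )
        )
    return out


def estimate_grf(
    model: ModelDef,
    motion: MotionTrajectory,
    aero_loads: list[ExternalLoad] | None = None,
    config: GRFConfig | None = None,
    feet: tuple[str, str] = ("foot_l", "foot_r"),
) -> GRFResult:
    """Iterate inverse dynamics, redistributing pelvis residuals to the feet.

    Left and right legs receive identical updates (half of each residual
    component), so their trajectories remain exactly equal throughout.
    Returns a result whose ``converged`` flag reflects whether the mean RMS
    of the actively updated residual components fell below the threshold.
    """
    cfg = config or GRFConfig()
    comp = CompiledModel(model)
    for seg in feet:
        if cfg.station not in model.segment(seg).stations:
            raise ValueError(
                f"segment {seg!r} has no station {cfg.station!r} "
                "(GRF application point)"
            )
    if motion.qddot is None:
        raise ValueError("motion must carry qddot (run differentiate first)")

    n = motion.n_frames
    state = GRFState(times=motion.times.copy(), left=np.zeros((n, 6)),
                     right=np.zeros((n, 6)), iteration=0)
    active_idx = [WRENCH_COMPONENTS.index(c) for c in cfg.active]
    aero_loads = aero_loads or []

    history: list[float] = []
    converged = False
    diverging = 0
    gf = None
    for s in range(1, cfg.max_iterations + 1):
        loads = aero_loads + grf_external_loads(model, state, cfg.station, feet)
        gf = inverse_dynamics(comp, motion, loads)
        res = gf.residual.data
        metric = mean_rms_residual(res, cfg.active)
        history.append(metric)
        if metric < cfg.threshold:
            converged = True
            state.iteration = s
            break
        if len(history) >= 2 and metric > history[-2]:
            diverging += 1
            if diverging >= cfg.divergence_patience:
                warnings.warn(
                    f"GRF iteration diverging: mean RMS rose for "
                    f"{diverging} consecutive iterations (now {metric:.3g})"
                )
                state.iteration = s
                break
        else:
            diverging = 0
        # Residual redistribution: half of each residual component is added
        # to the corresponding component of each leg.
        if cfg.mode == "full12":
            state.left[:, active_idx] += 0.5 * res[:, active_idx]
            state.right[:, active_idx] += 0.5 * res[:, active_idx]
        else:
            state.left[:, 1] += 0.5 * res[:, 1]
            state.right[:, 1] += 0.5 * res[:, 1]
            state.left[:, 0] = cfg.friction_sign * cfg.mu * state.left[:, 1]
            state.right[:, 0] = cfg.friction_sign * cfg.mu * state.right[:, 1]
        state.iteration = s
    else:
        warnings.warn(
            f"GRF estimation did not converge in {cfg.max_iterations} "
            f"iterations (mean RMS {history[-1]:.3g} >= {cfg.threshold})"
        )

    negative_fy = np.nonzero(state.left[:, 1] < 0)[0].tolist()
    if negative_fy:
        warnings.warn(
            f"estimated vertical GRF negative in frames {negative_fy} "
            "(no unilateral constraint is imposed)"
        )
    return GRFResult(
        state=state,
        residual_history=history,
        converged=converged,
        iterations=state.iteration,
        final_residual=gf.residual,
        generalized_forces=gf,
        metadata={
            "mode": cfg.mode,
            "threshold": cfg.threshold,
            "mu": cfg.mu,
            "active_components": list(cfg.active),
            "negative_fy_frames": negative_fy,
        },
    )


def compare_grf(
    estimated: GRFResult | tuple[np.ndarray, np.ndarray],
    measured: tuple[np.ndarray, np.ndarray],
    body_weight: float | None = None,
) -> dict[str, float]:
    """Per-axis RMSE between estimated and measured total ground forces.

    ``measured`` is (times, forces(n, 3)); it is linearly resampled onto the
    estimated time base (force plates typically sample faster).  With
    ``body_weight`` (N) given, RMSE is also reported normalized to BW.
    """
    if isinstance(estimated, GRFResult):
        t_est = estimated.state.times
        f_est = estimated.state.total_force
    else:
        t_est, f_est = estimated
        f_est = np.atleast_2d(np.asarray(f_est, dtype=float))
    t_mea, f_mea = measured
    t_mea = np.asarray(t_mea, dtype=float)
    f_mea = np.atleast_2d(np.asarray(f_mea, dtype=float))
    if t_est[0] < t_mea[0] - 1e-9 or t_est[-1] > t_mea[-1] + 1e-9:
        raise ValueError(
            "measured record does not cover the estimated time range"
        )
    out: dict[str, float] = {}
    for k, ax in enumerate("xyz"):
        res = np.interp(t_est, t_mea, f_mea[:, k]) - f_est[:, k]
        rmse = float(np.sqrt(np.mean(res**2)))
        out[f"rmse_{AXIS_NAMES[ax]}_N"] = rmse
        if body_weight:
            out[f"rmse_{AXIS_NAMES[ax]}_bw"] = rmse / body_weight
    return out
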