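"""End-to-end take-off processing: markers -> kinematics -> loads -> muscles.

Mirrors the field workflow: inverse kinematics on the joint-point
trajectories, filtering and differentiation, posture-angle extraction and
aerodynamic load lookup, iterative GRF estimation, and static optimization.
Every stage writes its tables to the output directory and contributes to a
JSON run report.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .aero import apply_aero_loads
from .grf import GRFConfig, estimate_grf
from .kinematics import differentiate, extract_posture_angles, inverse_kinematics
from .model import load_model, scale_model
from .muscles import DEFAULT_GROUPS, static_optimization, torque_contributions

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Settings of one processing run (serializable round trip)."""

    model_path: str
    markers_path: str
    output_dir: str
    aero_db_path: str | None = None
    subject_height: float | None = None  # m; None = no scaling
    subject_mass: float | None = None  # kg
    strength_doubling: bool = True
    filter_cutoff_hz: float | None = 10.0
    grf_mode: str = "takeoff_constrained"
    grf_mu: float = 0.018
    grf_threshold: float = 0.001
    grf_max_iterations: int = 500
    approach_speed: float | None = None  # m/s; None = COM speed per frame
    air_density: float | None = None  # kg/m^3; None = database reference
    force_model: str = "ideal"
    seed: int = 0
    log_level: str = "info"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    def validate(self) -> None:
        for key in ("model_path", "markers_path"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        if self.aero_db_path is not None and not Path(self.aero_db_path).exists():
            raise FileNotFoundError(f"aero_db_path: {self.aero_db_path} "
                                    "does not exist")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return the run report (also written as
    ``report.json``).  Raises :class:`PipelineError` naming the failed stage.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "config": dict(config.__dict__)}

    def stage(name):
        def deco(fn):
            try:
                r = fn()
                report["stages"].append(name)
                return r
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, f"{e}\n{traceback.format_exc()}") from e
        return deco

    @stage("load_model")
    def model():
        m = load_model(config.model_path)
        if config.subject_height is not None and config.subject_mass is not None:
            m = scale_model(m, config.subject_height, config.subject_mass,
                            strength_doubling=config.strength_doubling)
        return m

    @stage("load_aero_db")
    def db():
        if config.aero_db_path is None:
            return None
        p = Path(config.aero_db_path)
        if p.suffix in (".h5", ".hdf5"):
            return mio.read_aero_hdf5(p)
        return mio.read_aero_csv(p)

    @stage("inverse_kinematics")
    def ik():
        markers = mio.read_trc(config.markers_path)
        motion = inverse_kinematics(model, markers)
        mio.write_motion(motion, out / "ik_motion.sto")
        report["mean_rms_marker_error_m"] = motion.metadata[
            "mean_rms_marker_error"]
        report["nonconverged_ik_frames"] = motion.metadata["nonconverged_frames"]
        return motion

    @stage("differentiate")
    def motion():
        m = differentiate(ik, cutoff_hz=config.filter_cutoff_hz)
        mio.write_motion(m, out / "motion_filtered.sto")
        return m

    @stage("posture_angles")
    def postures():
        pa = extract_posture_angles(model, motion)
        import pandas as pd

        pd.DataFrame([p.as_dict() for p in pa]).assign(
            time=motion.times
        ).to_csv(out / "posture_angles.csv", index=False)
        return pa

    @stage("aero_loads")
    def aero():
        if db is None:
            return None
        al = apply_aero_loads(
            model, motion, db, speed=config.approach_speed,
            rho=config.air_density, postures=postures,
        )
        mio.write_external_loads(al.loads, out / "aero_loads.mot", motion.times)
        np.savetxt(
            out / "aero_whole_body.csv",
            np.column_stack([motion.times, al.whole_body_force]),
            delimiter=",", header="time,fx,fy,fz", comments="",
        )
        report["aero_peak_drag_N"] = float(np.abs(al.whole_body_force[:, 0]).max())
        return al

    @stage("grf_estimation")
    def grf():
        cfg = GRFConfig(
            threshold=config.grf_threshold,
            max_iterations=config.grf_max_iterations,
            mode=config.grf_mode,
            mu=config.grf_mu,
        )
        res = estimate_grf(
            model, motion, aero_loads=(aero.loads if aero else None), config=cfg
        )
        from .grf import grf_external_loads

        mio.write_external_loads(
            grf_external_loads(model, res.state), out / "grf.mot", motion.times
        )
        mio.write_grf_report(res, out / "grf_report.json")
        report["grf_converged"] = bool(res.converged)
        report["grf_iterations"] = int(res.iterations)
        report["grf_final_mean_rms_residual"] = float(res.final_mean_rms)
        if not res.converged:
            raise PipelineError(
                "grf_estimation",
                f"did not converge (mean RMS {res.final_mean_rms:.3g})",
            )
        return res

    @stage("static_optimization")
    def muscles():
        sol = static_optimization(
            model, motion, grf.generalized_forces, force_model=config.force_model
        )
        mio.write_sto(out / "activations.sto", sol.times, sol.activations,
                      sol.muscle_names, header={"contents": "activations"})
        mio.write_sto(out / "muscle_forces.sto", sol.times, sol.forces,
                      sol.muscle_names, header={"units": "N"})
        mio.write_sto(out / "reserves.sto", sol.times, sol.reserves,
                      sol.coordinate_names, header={"units": "N m"})
        tc = torque_contributions(sol, DEFAULT_GROUPS)
        groups = {
            g: {c: arr[:, k].tolist()
                for k, c in enumerate(sol.coordinate_names)}
            for g, arr in tc.get("groups", {}).items()
        }
        (out / "muscle_groups.json").write_text(json.dumps(groups, indent=1))
        report["peak_reserve_Nm"] = float(np.abs(sol.reserves).max())
        report["max_kkt_residual"] = float(sol.kkt_residual.max())
        return sol

    report["outputs"] = sorted(p.name for p in out.iterdir())
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
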