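"""Readers and writers for the motion-capture text dialects and databases.

Supported formats:

* ``.trc``  — tab-delimited marker trajectories (DataRate/NumFrames header,
  per-marker X/Y/Z triplets), the mocap interchange convention.
* ``.sto`` / ``.mot`` — tab-delimited time-series tables with a header block
  terminated by ``endheader``; time is the first column.  Angles are stored
  in degrees (``inDegrees=yes``), radians in memory.
* external-loads ``.mot`` — the conventional nine columns per load (force
  xyz, point xyz, torque xyz).
* aerodynamic database — long-form CSV (one row per posture x part) with
  ``#`` reference-condition headers, or an HDF5 container with grid
  metadata.

Every writer emits provenance/units headers; re-reading a written file
reproduces the in-memory values to full precision (floats are serialized
with repr round-trip precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .aero import ANGLE_ORDER, PART_NAMES, AeroDatabase, AeroRecord, GridBlock
from .dynamics import ExternalLoad
from .kinematics import MarkerTrajectory, MotionTrajectory, PostureAngles
from .model import ModelDef, rotational_mask

__all__ = [
    "read_trc", "write_trc",
    "read_sto", "write_sto",
    "read_motion", "write_motion",
    "read_external_loads", "write_external_loads",
    "read_aero_csv", "write_aero_csv",
    "read_aero_hdf5", "write_aero_hdf5",
    "write_grf_report",
]

_FMT = "%.17g"  # round-trip precision


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------


def write_trc(markers: MarkerTrajectory, path: str | Path, units: str = "m") -> None:
    path = Path(path)
    rate = markers.rate
    n, nm = markers.n_frames, len(markers.names)
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
        "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{_FMT % rate}\t{_FMT % rate}\t{n}\t{nm}\t{units}\t{_FMT % rate}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(markers.names) + "\t\t",
        "\t\t" + "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(nm)
        ),
        "",
    ]
    for f in range(n):
        row = [str(f + 1), _FMT % markers.times[f]]
        for m in range(nm):
            row.extend(_FMT % v for v in markers.positions[f, m])
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_trc(path: str | Path) -> MarkerTrajectory:
    lines = Path(path).read_text().splitlines()
    meta_names = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_names, meta_vals))
    nm = int(meta["NumMarkers"])
    names = [s for s in lines[3].split("\t")[2:] if s.strip()]
    if len(names) != nm:
        raise ValueError(f"{path}: header lists {len(names)} markers, "
                         f"NumMarkers={nm}")
    times, pos = [], []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        times.append(float(parts[1]))
        vals = [float(v) if v.strip() else np.nan for v in parts[2:2 + 3 * nm]]
        pos.append(np.array(vals).reshape(nm, 3))
    return MarkerTrajectory(names=names, times=np.array(times),
                            positions=np.array(pos))


# ---------------------------------------------------------------------------
# STO / MOT tables
# ---------------------------------------------------------------------------


def write_sto(
    path: str | Path,
    times: np.ndarray,
    data: np.ndarray,
    names: list[str],
    header: dict | None = None,
) -> None:
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    lines = [path.stem, "version=1"]
    for k, v in (header or {}).items():
        lines.append(f"{k}={v}")
    lines += [f"nRows={len(times)}", f"nColumns={1 + len(names)}", "endheader"]
    lines.append("\t".join(["time"] + list(names)))
    for f in range(len(times)):
        lines.append("\t".join([_FMT % times[f]] + [_FMT % v for v in data[f]]))
    path.write_text("\n".join(lines) + "\n")


def read_sto(path: str | Path):
    """Returns (times, data, names, header dict)."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if line.strip() == "endheader":
            break
        if "=" in line:
            k, v = line.split("=", 1)
            header[k.strip()] = v.strip()
    names = lines[i + 1].split("\t")
    rows = [
        [float(v) for v in line.split("\t")]
        for line in lines[i + 2:] if line.strip()
    ]
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1:], names[1:], header


def write_motion(motion: MotionTrajectory, path: str | Path,
                 what: str = "q") -> None:
    """Write q (or qdot/qddot) with rotational coordinates in degrees."""
    data = {"q": motion.q, "qdot": motion.qdot, "qddot": motion.qddot}[what]
    if data is None:
        raise ValueError(f"motion has no {what}")
    rot = motion.rotational or [False] * data.shape[1]
    out = data.copy()
    for j, r in enumerate(rot):
        if r:
            out[:, j] = np.degrees(out[:, j])
    write_sto(
        path, motion.times, out, motion.coordinate_names,
        header={
            "inDegrees": "yes",
            "rotationalColumns": ",".join("1" if r else "0" for r in rot),
            "contents": what,
        },
    )


def read_motion(path: str | Path, model: ModelDef | None = None) -> MotionTrajectory:
    times, data, names, header = read_sto(path)
    if model is not None:
        rot = rotational_mask(model)
    elif "rotationalColumns" in header:
        rot = [c == "1" for c in header["rotationalColumns"].split(",")]
    else:
        rot = [False] * len(names)
    if header.get("inDegrees", "no") == "yes":
        data = data.copy()
        for j, r in enumerate(rot):
            if r:
                data[:, j] = np.radians(data[:, j])
    return MotionTrajectory(coordinate_names=names, times=times, q=data,
                            rotational=rot, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# external loads (nine columns per load)
# ---------------------------------------------------------------------------


def write_external_loads(
    loads: list[ExternalLoad], path: str | Path, times: np.ndarray | None = None
) -> None:
    names, cols, spec = [], [], []
    for ld in loads:
        nm = ld.name or f"load_{ld.segment}"
        for c in ("force_x", "force_y", "force_z",
                  "point_x", "point_y", "point_z",
                  "torque_x", "torque_y", "torque_z"):
            names.append(f"{nm}_{c}")
        cols.append(np.hstack([ld.force, ld.point, ld.torque]))
        spec.append(f"{nm}:{ld.segment}:{ld.point_frame}")
    if times is None:
        times = np.arange(loads[0].n_frames, dtype=float)
    write_sto(path, times, np.hstack(cols), names, header={"loads": ";".join(spec)})


def read_external_loads(path: str | Path) -> tuple[np.ndarray, list[ExternalLoad]]:
    times, data, names, header = read_sto(path)
    out = []
    specs = header.get("loads", "")
    for k, entry in enumerate(s for s in specs.split(";") if s):
        nm, segment, point_frame = entry.split(":")
        block = data[:, 9 * k: 9 * (k + 1)]
        out.append(
            ExternalLoad(
                segment=segment, force=block[:, 0:3], point=block[:, 3:6],
                torque=block[:, 6:9], point_frame=point_frame, name=nm,
            )
        )
    return times, out


# ---------------------------------------------------------------------------
# aerodynamic database
# ---------------------------------------------------------------------------

_AERO_COLS = ["phase", "delta2", "delta3", "theta2", "theta1", "delta4",
              "delta1", "alpha", "part", "fx", "fy", "fz", "mx", "my", "mz"]


def write_aero_csv(db: AeroDatabase, path: str | Path) -> None:
    rows = []
    for rec in db.records():
        p = rec.posture
        for part in PART_NAMES:
            rows.append([
                rec.phase, p.delta2, p.delta3, p.theta2, p.theta1, p.delta4,
                p.delta1, p.alpha, part, *rec.forces[part], *rec.moments[part],
            ])
    df = pd.DataFrame(rows, columns=_AERO_COLS)
    with open(path, "w") as fh:
        fh.write(f"# ref_height={_FMT % db.ref_height}\n")
        fh.write(f"# ref_speed={_FMT % db.ref_speed}\n")
        fh.write(f"# ref_rho={_FMT % db.ref_rho}\n")
        fh.write(f"# provenance={db.provenance}\n")
        df.to_csv(fh, index=False, float_format=_FMT)


def read_aero_csv(path: str | Path) -> AeroDatabase:
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            k, v = line[1:].strip().split("=", 1)
            header[k.strip()] = v.strip()
        fh.seek(pos)
        df = pd.read_csv(fh)
    records = []
    for (phase, *angles), grp in df.groupby(
        ["phase"] + _AERO_COLS[1:8], sort=False
    ):
        d2, d3, t2, t1, d4, d1, al = angles
        posture = PostureAngles(delta1=d1, delta2=d2, delta3=d3, delta4=d4,
                                theta1=t1, theta2=t2, alpha=al)
        forces = {}
        moments = {}
        for _, row in grp.iterrows():
            forces[row["part"]] = row[["fx", "fy", "fz"]].to_numpy(dtype=float)
            moments[row["part"]] = row[["mx", "my", "mz"]].to_numpy(dtype=float)
        records.append(
            AeroRecord(
                posture=posture, forces=forces, moments=moments, phase=phase,
                ref_height=float(header.get("ref_height", 1.70)),
                ref_speed=float(header.get("ref_speed", 23.0)),
                ref_rho=float(header.get("ref_rho", 1.225)),
            )
        )
    return AeroDatabase.from_records(
        records, provenance=header.get("provenance", "")
    )


def write_aero_hdf5(db: AeroDatabase, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["ref_height"] = db.ref_height
        h5.attrs["ref_speed"] = db.ref_speed
        h5.attrs["ref_rho"] = db.ref_rho
        h5.attrs["provenance"] = db.provenance
        h5.attrs["parts"] = list(PART_NAMES)
        for k, (gb, data) in enumerate(db.blocks):
            g = h5.create_group(f"block_{k}")
            g.attrs["phase"] = gb.phase
            g.attrs["delta2"] = gb.delta2
            for a in ANGLE_ORDER:
                g.attrs[f"axis_{a}"] = list(gb.axes[a])
            g.create_dataset("data", data=data)


def read_aero_hdf5(path: str | Path) -> AeroDatabase:
    import h5py

    blocks = []
    with h5py.File(path, "r") as h5:
        refs = {k: float(h5.attrs[k]) for k in ("ref_height", "ref_speed", "ref_rho")}
        prov = str(h5.attrs.get("provenance", ""))
        for k in sorted(h5.keys(), key=lambda s: int(s.split("_")[1])):
            g = h5[k]
            axes = {a: tuple(float(v) for v in g.attrs[f"axis_{a}"])
                    for a in ANGLE_ORDER}
            gb = GridBlock(str(g.attrs["phase"]), float(g.attrs["delta2"]), axes)
            blocks.append((gb, g["data"][()]))
    return AeroDatabase(blocks, provenance=prov, **refs)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_grf_report(result, path: str | Path) -> None:
    """JSON run report of a GRF estimation (iterations, residuals, flags)."""
    report = {
        "converged": bool(result.converged),
        "iterations": int(result.iterations),
        "final_mean_rms_residual": float(result.final_mean_rms),
        "residual_history": [float(v) for v in result.residual_history],
        **{k: v for k, v in result.metadata.items()},
    }
    Path(path).write_text(json.dumps(report, indent=1))
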