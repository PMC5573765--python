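"""File-format plumbing: CSV waveforms, JSON parameter sets, ascii PLY
surface meshes with a per-face region property, and HDF5 / CSV-directory
snapshot series.

Clinical units (mmHg, mL/s) are used for Windkessel parameter files,
matching how such values are reported; everything else is SI.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

import h5py
import numpy as np

from .inflow import FourierWaveform, SampledWaveform
from .lumped import InternalElements, NetworkSolution, WindkesselSet, WindkesselTerminal
from .wall_analysis import SpaceTimeVectorField, SurfaceMesh

__all__ = [
    "MMHG_PER_PA",
    "read_waveform_csv",
    "write_waveform_csv",
    "fourier_waveform_to_json",
    "fourier_waveform_from_json",
    "read_windkessel_json",
    "write_windkessel_json",
    "load_table1",
    "write_solution_csv",
    "write_ply",
    "read_ply",
    "write_rings_json",
    "read_rings_json",
    "write_field_h5",
    "read_field_h5",
    "write_field_csv_dir",
    "read_field_csv_dir",
    "read_centreline_csv",
    "write_centreline_csv",
]

MMHG_PER_PA = 1.0 / 133.322


# --------------------------------------------------------------------------
# waveforms

def read_waveform_csv(path, units: str = "") -> SampledWaveform:
    """Read a `time_s,value` CSV (header required)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["time_s", "value"]:
            raise ValueError(f"{path}: expected header 'time_s,value'")
        rows = [(float(r[0]), float(r[1])) for r in reader if r]
    t, v = zip(*rows)
    return SampledWaveform(np.array(t), np.array(v), units=units)


def write_waveform_csv(path, w: SampledWaveform) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(w.times, w.values):
            writer.writerow([f"{t:.10g}", f"{v:.10g}"])


def fourier_waveform_to_json(wf: FourierWaveform) -> dict:
    return {
        "period_s": wf.period,
        "mean": wf.mean_flow,
        "harmonics": [{"re": c.real, "im": c.imag} for c in wf.harmonics],
    }


def fourier_waveform_from_json(obj: dict) -> FourierWaveform:
    return FourierWaveform(
        period=obj["period_s"],
        mean_flow=obj["mean"],
        harmonics=tuple(complex(h["re"], h["im"]) for h in obj["harmonics"]),
    )


# --------------------------------------------------------------------------
# Windkessel / internal element parameter files (clinical units)

def _terminal_to_dict(t: WindkesselTerminal) -> dict:
    return {"R1": t.R1, "R2": t.R2, "C": t.C}


def write_windkessel_json(path, wk: WindkesselSet, internal: InternalElements | None = None) -> None:
    obj = {
        "units": {"R": "mmHg.mL-1.s", "C": "mL.mmHg-1",
                  "L": "mmHg.mL-1.s2", "Rq": "mmHg.mL-2.s2"},
        "windkessel": {
            "rao": _terminal_to_dict(wk.rao),
            "uao": _terminal_to_dict(wk.uao),
            "vo": _terminal_to_dict(wk.vo),
            "tie_rao_uao": wk.tie_rao_uao,
        },
    }
    if internal is not None:
        obj["internal"] = {
            k: getattr(internal, k) for k in ("L1A", "L2A", "L1V", "R1A", "R2A", "R1V")
        }
    Path(path).write_text(json.dumps(obj, indent=2))


def read_windkessel_json(path) -> tuple[WindkesselSet, InternalElements | None]:
    obj = json.loads(Path(path).read_text())
    wko = obj["windkessel"]
    wk = WindkesselSet(
        rao=WindkesselTerminal(**wko["rao"]),
        uao=WindkesselTerminal(**wko["uao"]),
        vo=WindkesselTerminal(**wko["vo"]),
        tie_rao_uao=wko.get("tie_rao_uao", True),
    )
    internal = None
    if "internal" in obj:
        internal = InternalElements(**obj["internal"])
    return wk, internal


def load_table1(column: str = "P1-IN") -> WindkesselSet:
    """Packaged Windkessel parameter fixture; column 'P1-IN' or 'P2-IN'."""
    text = resources.files("avflow.data").joinpath("table1.json").read_text()
    table = json.loads(text)
    if column not in table:
        raise KeyError(f"unknown column {column!r}; have {sorted(table)}")
    col = table[column]
    return WindkesselSet(
        rao=WindkesselTerminal(**col["rao"]),
        uao=WindkesselTerminal(**col["uao"]),
        vo=WindkesselTerminal(**col["vo"]),
        tie_rao_uao=True,
    )


def write_solution_csv(path, sol: NetworkSolution) -> None:
    """One column per node pressure / branch flow of the final cycle."""
    names_p = sorted(sol.node_pressures)
    names_q = sorted(sol.branch_flows)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s"] + names_p + names_q)
        for i, t in enumerate(sol.times):
            row = [f"{t:.10g}"]
            row += [f"{sol.node_pressures[n][i]:.10g}" for n in names_p]
            row += [f"{sol.branch_flows[n][i]:.10g}" for n in names_q]
            writer.writerow(row)


# --------------------------------------------------------------------------
# surface meshes: ascii PLY with a per-face integer `region` property

_REGION_CODE = {"artery": 0, "vein": 1, "other": 2}
_CODE_REGION = {v: k for k, v in _REGION_CODE.items()}


def write_ply(path, mesh: SurfaceMesh, face_scalar: np.ndarray | None = None,
              scalar_name: str = "quality") -> None:
    """Ascii PLY with vertices, faces, a per-face region code, and an
    optional extra per-face scalar (e.g. a quad-map label code)."""
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.vertices.shape[0]}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "property int region",
    ]
    if face_scalar is not None:
        lines.append(f"property double {scalar_name}")
    lines.append("end_header")
    for v in mesh.vertices:
        lines.append(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}")
    for i, f in enumerate(mesh.faces):
        row = f"3 {f[0]} {f[1]} {f[2]} {_REGION_CODE[str(mesh.region[i])]}"
        if face_scalar is not None:
            row += f" {face_scalar[i]:.12g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_ply(path) -> tuple[SurfaceMesh, np.ndarray | None]:
    """Read the ascii PLY dialect written by :func:`write_ply`.

    Returns the mesh and the optional extra per-face scalar (or None).
    """
    text = Path(path).read_text().splitlines()
    it = iter(text)
    if next(it).strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vert = n_face = 0
    face_props: list[str] = []
    current = None
    for line in it:
        tok = line.split()
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise ValueError("only ascii PLY is supported")
        elif tok[0] == "element":
            current = tok[1]
            if tok[1] == "vertex":
                n_vert = int(tok[2])
            elif tok[1] == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and current == "face" and tok[1] != "list":
            face_props.append(tok[2])
        elif tok[0] == "end_header":
            break
    verts = np.array(
        [[float(x) for x in next(it).split()[:3]] for _ in range(n_vert)]
    )
    faces = np.empty((n_face, 3), dtype=np.int64)
    region = np.empty(n_face, dtype=object)
    has_scalar = len(face_props) > 1
    scalar = np.empty(n_face) if has_scalar else None
    for i in range(n_face):
        tok = next(it).split()
        if tok[0] != "3":
            raise ValueError("only triangle faces are supported")
        faces[i] = [int(tok[1]), int(tok[2]), int(tok[3])]
        region[i] = _CODE_REGION[int(tok[4])]
        if has_scalar:
            scalar[i] = float(tok[5])
    return SurfaceMesh(vertices=verts, faces=faces, region=region), scalar


def write_rings_json(path, rings: dict) -> None:
    Path(path).write_text(
        json.dumps({k: np.asarray(v).tolist() for k, v in rings.items()}, indent=0)
    )


def read_rings_json(path) -> dict:
    obj = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=np.int64) for k, v in obj.items()}


# --------------------------------------------------------------------------
# snapshot series: HDF5 (`times`, `vectors[n_t, n_faces, 3]`) or a
# CSV-per-snapshot directory with an index file

def write_field_h5(path, field: SpaceTimeVectorField) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=field.times)
        fh.create_dataset("vectors", data=field.vectors)


def read_field_h5(path, mesh: SurfaceMesh) -> SpaceTimeVectorField:
    with h5py.File(path, "r") as fh:
        times = fh["times"][:]
        vectors = fh["vectors"][:]
    return SpaceTimeVectorField(mesh=mesh, times=times, vectors=vectors)


def write_field_csv_dir(path, field: SpaceTimeVectorField) -> None:
    """One CSV per snapshot (`sx,sy,sz` rows per face) plus `times.csv`."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "times.csv", field.times, header="time_s", comments="")
    for i in range(field.times.size):
        np.savetxt(
            d / f"snapshot_{i:05d}.csv",
            field.vectors[i],
            delimiter=",",
            header="sx,sy,sz",
            comments="",
        )


def read_field_csv_dir(path, mesh: SurfaceMesh) -> SpaceTimeVectorField:
    d = Path(path)
    times = np.loadtxt(d / "times.csv", skiprows=1, ndmin=1)
    vectors = np.stack(
        [
            np.loadtxt(d / f"snapshot_{i:05d}.csv", delimiter=",", skiprows=1)
            for i in range(times.size)
        ]
    )
    return SpaceTimeVectorField(mesh=mesh, times=times, vectors=vectors)


# --------------------------------------------------------------------------
# centrelines

def read_centreline_csv(path):
    from .geometry import Centreline

    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 4:
        raise ValueError(f"{path}: expected columns x,y,z,radius")
    return Centreline(points=data[:, :3], radius=data[:, 3])


def write_centreline_csv(path, c) -> None:
    data = np.column_stack([c.points, c.radius])
    np.savetxt(path, data, delimiter=",", header="x,y,z,radius", comments="")
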