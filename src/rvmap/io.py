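"""File formats: PLY / legacy-VTK / OFF meshes, CSV field matrices and tables.

Meshes travel as PLY (ASCII or binary little-endian) with optional per-vertex
unit normals and the integer region attribute ``region``; OFF is read-only.
Legacy VTK polydata (ASCII) is written for visualisation with per-vertex
scalar arrays attached as POINT_DATA. Per-vertex fields and subjects x
vertices matrices round-trip through CSV with %.17g floats and round-trip
parsing, so read(write(x)) is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .mesh import REGION_NAMES, SurfaceMesh, VentricularShell, VertexField
from .simulate import VertexFieldMatrix

__all__ = ["write_ply", "read_mesh", "write_vtk_polydata", "read_vtk_polydata",
           "write_vertex_field", "read_vertex_field", "write_field_matrix",
           "read_field_matrix", "write_subject_table", "read_subject_table",
           "SchemaError"]


class SchemaError(ValueError):
    """A table does not match its declared column schema."""


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

def write_ply(path: str | Path, mesh: SurfaceMesh,
              region: np.ndarray | None = None, binary: bool = False) -> None:
    """PLY with x/y/z, nx/ny/nz and (optionally) the int region attribute."""
    path = Path(path)
    V, F = mesh.n_vertices, len(mesh.faces)
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {V}"]
    header += [f"property double {p}" for p in ("x", "y", "z", "nx", "ny", "nz")]
    if region is not None:
        header.append("property int region")
    header += [f"element face {F}",
               "property list uchar int vertex_indices",
               "end_header"]
    vert_cols = np.hstack([mesh.vertices, mesh.normals])
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fields = [(p, "<f8") for p in ("x", "y", "z", "nx", "ny", "nz")]
            if region is not None:
                fields.append(("region", "<i4"))
            rec = np.empty(V, dtype=fields)
            for j, (name, _) in enumerate(fields[:6]):
                rec[name] = vert_cols[:, j]
            if region is not None:
                rec["region"] = np.asarray(region, dtype="<i4")
            fh.write(rec.tobytes())
            frec = np.empty(F, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
            frec["n"] = 3
            frec["idx"] = mesh.faces
            fh.write(frec.tobytes())
        else:
            lines = []
            for i in range(V):
                row = " ".join(repr(float(x)) for x in vert_cols[i])
                if region is not None:
                    row += f" {int(region[i])}"
                lines.append(row)
            for f in mesh.faces:
                lines.append(f"3 {f[0]} {f[1]} {f[2]}")
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def read_mesh(path: str | Path) -> tuple[SurfaceMesh, np.ndarray | None]:
    """Load PLY (ascii/binary) or OFF; returns (mesh, region labels or None).

    Stored unit normals and the ``region`` attribute are recovered from PLY
    files written by this package (or any PLY carrying those properties).
    """
    path = Path(path)
    tm = trimesh.load(str(path), process=False, force="mesh")
    normals = None
    region = None
    raw = tm.metadata.get("_ply_raw")
    if raw and "vertex" in raw:
        data = raw["vertex"]["data"]
        names = raw["vertex"]["properties"].keys()
        if all(k in names for k in ("nx", "ny", "nz")):
            normals = np.column_stack([np.asarray(data[k], dtype=float).ravel()
                                       for k in ("nx", "ny", "nz")])
            lens = np.linalg.norm(normals, axis=1)
            if not np.allclose(lens, 1.0, atol=1e-5):
                normals = None
            else:
                normals /= lens[:, None]
        if "region" in names:
            region = np.asarray(data["region"], dtype=np.int64).ravel()
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), normals)
    return mesh, region


# ---------------------------------------------------------------------------
# legacy VTK polydata (ASCII)
# ---------------------------------------------------------------------------

def write_vtk_polydata(path: str | Path, mesh: SurfaceMesh,
                       point_data: dict[str, np.ndarray] | None = None) -> None:
    path = Path(path)
    V, F = mesh.n_vertices, len(mesh.faces)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nrvmap surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {V} double\n")
        for p in mesh.vertices:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        fh.write(f"POLYGONS {F} {4 * F}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {V}\n")
            for name, values in point_data.items():
                values = np.asarray(values)
                if values.dtype.kind in "iub":
                    fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(str(int(v)) for v in values) + "\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(repr(float(v)) for v in values) + "\n")


def read_vtk_polydata(path: str | Path) -> tuple[SurfaceMesh, dict[str, np.ndarray]]:
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    verts = faces = None
    point_data: dict[str, np.ndarray] = {}
    while i < len(lines):
        line = lines[i].strip()
        parts = line.split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            vals: list[float] = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            verts = np.asarray(vals).reshape(n, 3)
        elif key == "POLYGONS":
            n = int(parts[1])
            vals = []
            i += 1
            while i < len(lines) and len(vals) < int(parts[2]):
                vals.extend(int(x) for x in lines[i].split())
                i += 1
            arr = np.asarray(vals, dtype=np.int64)
            faces_list = []
            j = 0
            while j < len(arr):
                k = arr[j]
                if k != 3:
                    raise ValueError("only triangle polydata is supported")
                faces_list.append(arr[j + 1:j + 4])
                j += k + 1
            faces = np.vstack(faces_list)
        elif key == "SCALARS":
            name = parts[1]
            dtype = float if parts[2].lower() in ("double", "float") else int
            i += 2  # skip LOOKUP_TABLE line
            vals = []
            n = len(verts)
            while len(vals) < n:
                vals.extend(dtype(x) for x in lines[i].split())
                i += 1
            point_data[name] = np.asarray(vals)
        else:
            i += 1
    if verts is None or faces is None:
        raise ValueError(f"{path}: not a triangle polydata file")
    return SurfaceMesh(verts, faces), point_data


def write_shell(dirpath: str | Path, shell: VentricularShell,
                binary: bool = False) -> None:
    """Convenience: endo/epi PLY pair with region labels."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    tag = f"{shell.subject_id}_{shell.phase}"
    write_ply(dirpath / f"{tag}_endo.ply", shell.endo, shell.region_labels, binary)
    write_ply(dirpath / f"{tag}_epi.ply", shell.epi, shell.region_labels, binary)


# ---------------------------------------------------------------------------
# CSV fields and tables
# ---------------------------------------------------------------------------

def write_vertex_field(path: str | Path, field: VertexField) -> None:
    df = pd.DataFrame({"vertex_id": np.arange(len(field)),
                       "value": field.values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_vertex_field(path: str | Path, units: str = "", name: str = "") -> VertexField:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["vertex_id", "value"]:
        raise SchemaError(f"{path}: expected columns vertex_id,value")
    return VertexField(df["value"].to_numpy(), units=units, name=name)


def write_field_matrix(path: str | Path, matrix: VertexFieldMatrix) -> None:
    ids = matrix.subject_ids or [f"S{i:04d}" for i in range(matrix.n_subjects)]
    df = pd.DataFrame(matrix.values, index=pd.Index(ids, name="subject_id"),
                      columns=[f"v{j:05d}" for j in range(matrix.n_vertices)])
    df.to_csv(path, float_format="%.17g")


def read_field_matrix(path: str | Path, name: str = "", units: str = "") -> VertexFieldMatrix:
    df = pd.read_csv(path, index_col="subject_id", float_precision="round_trip")
    return VertexFieldMatrix(df.to_numpy(dtype=np.float64), name=name,
                             units=units, subject_ids=list(df.index))


SUBJECT_SCHEMA = {
    "subject_id": "str", "age": "float", "sex": "str", "ethnicity": "str",
    "ph_group": "str", "bsa": "float", "mpap": "float", "spap": "float",
    "time_from_diagnosis": "float", "creatinine": "float", "bilirubin": "float",
}
SUBJECT_UNITS = {
    "age": "years", "bsa": "m^2", "mpap": "mmHg", "spap": "mmHg",
    "time_from_diagnosis": "months", "creatinine": "umol/L",
    "bilirubin": "umol/L", "time_months": "months",
}


def write_subject_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.17g")
    units = {c: SUBJECT_UNITS[c] for c in table.columns if c in SUBJECT_UNITS}
    Path(str(path) + ".units.json").write_text(json.dumps(units, indent=1))


def read_subject_table(path: str | Path,
                       required: tuple[str, ...] = tuple(SUBJECT_SCHEMA)) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
        kind = SUBJECT_SCHEMA.get(col)
        if kind == "float":
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise SchemaError(
                    f"{path}: column {col!r} has non-numeric value at row "
                    f"{bad.index[0]}")
            df[col] = df[col].astype(float)
        elif kind == "str":
            df[col] = df[col].astype(str)
    return df
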