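"""File formats: activation-map CSV, minimal ASCII VTU (XML unstructured
grid) export/import, JSON run configuration with schema validation and
content hashing, and HDF5 state checkpoints.

The VTU writer/reader covers exactly what this package produces: one Piece
of quad/hex cells with named point/cell data arrays, ascii-encoded.
"""
from __future__ import annotations

import hashlib
import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cv import ActivationPointCloud, CVField
from .mesh import TissueMesh

CSV_COLUMNS = ("x_mm", "y_mm", "z_mm", "at_ms")


def read_activation_csv(path) -> ActivationPointCloud:
    """Read a point cloud with header x_mm,y_mm,z_mm,at_ms; rows with
    non-finite entries are dropped (count reported via warning)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {', '.join(missing)}")
    vals = df[list(CSV_COLUMNS)].to_numpy(dtype=float)
    ok = np.isfinite(vals).all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} non-finite rows from {path}")
    return ActivationPointCloud(points=vals[ok, :3], at=vals[ok, 3])


def write_activation_csv(cloud: ActivationPointCloud, path) -> None:
    df = pd.DataFrame(np.column_stack([cloud.points, cloud.at]),
                      columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False)


def write_cv_csv(field: CVField, path) -> None:
    df = pd.DataFrame(
        np.column_stack([field.points, field.velocity, field.magnitude]),
        columns=["x_mm", "y_mm", "z_mm", "vx", "vy", "vz", "cv_m_per_s"])
    df["valid"] = field.valid.astype(int)
    df.to_csv(path, index=False)


# --- minimal ASCII VTU ---

_VTK_CELL = {4: 9, 8: 12}  # quad, hexahedron


def _fmt(arr) -> str:
    return " ".join(repr(x) if isinstance(x, float) else str(x)
                    for x in np.asarray(arr).ravel().tolist())


def write_vtu(path, mesh: TissueMesh, point_data: dict | None = None,
              cell_data: dict | None = None, meta: dict | None = None) -> None:
    """Write mesh + named arrays as an ascii VTU file.

    Arrays may be (n,), (n,3) or (ne, 3, 3) tensors (flattened to 9
    components).  ``meta`` is embedded as a FieldData string array.
    """
    n, ne = mesh.n_nodes, mesh.n_elems
    nn = mesh.elems.shape[1]
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             ' <UnstructuredGrid>']
    if meta:
        lines.append("  <FieldData>")
        payload = json.dumps(meta).replace("&", "&amp;").replace("<", "&lt;")
        lines.append(f'   <Array type="String" Name="cvep_meta">{payload}'
                     "</Array>")
        lines.append("  </FieldData>")
    lines.append(f'  <Piece NumberOfPoints="{n}" NumberOfCells="{ne}">')
    lines.append("   <Points>")
    lines.append('    <DataArray type="Float64" NumberOfComponents="3" '
                 f'format="ascii">{_fmt(mesh.nodes)}</DataArray>')
    lines.append("   </Points>")
    lines.append("   <Cells>")
    lines.append('    <DataArray type="Int64" Name="connectivity" '
                 f'format="ascii">{_fmt(mesh.elems)}</DataArray>')
    offs = np.arange(1, ne + 1) * nn
    lines.append('    <DataArray type="Int64" Name="offsets" '
                 f'format="ascii">{_fmt(offs)}</DataArray>')
    types = np.full(ne, _VTK_CELL[nn])
    lines.append('    <DataArray type="UInt8" Name="types" '
                 f'format="ascii">{_fmt(types)}</DataArray>')
    lines.append("   </Cells>")
    for tag, data in (("PointData", point_data), ("CellData", cell_data)):
        lines.append(f"   <{tag}>")
        for name, arr in (data or {}).items():
            a = np.asarray(arr, dtype=float)
            ncomp = 1 if a.ndim == 1 else int(np.prod(a.shape[1:]))
            lines.append(f'    <DataArray type="Float64" Name="{name}" '
                         f'NumberOfComponents="{ncomp}" format="ascii">'
                         f"{_fmt(a)}</DataArray>")
        lines.append(f"   </{tag}>")
    lines.append("  </Piece>")
    lines.append(" </UnstructuredGrid>")
    lines.append("</VTKFile>")
    Path(path).write_text("\n".join(lines))


def read_vtu(path):
    """Read back a VTU written by this package.

    Returns (nodes, elems, point_data, cell_data, meta).
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    meta_el = root.find(".//FieldData/Array[@Name='cvep_meta']")
    meta = json.loads(meta_el.text) if meta_el is not None and meta_el.text else {}

    def parse(el, dtype=float):
        vals = np.array((el.text or "").split(), dtype=dtype)
        ncomp = int(el.get("NumberOfComponents", "1"))
        return vals.reshape(-1, ncomp) if ncomp > 1 else vals

    nodes = parse(piece.find("Points/DataArray"))
    conn = parse(piece.find("Cells/DataArray[@Name='connectivity']"),
                 dtype=float).astype(np.int64)
    offs = parse(piece.find("Cells/DataArray[@Name='offsets']"),
                 dtype=float).astype(np.int64)
    nn = int(offs[0])
    elems = conn.reshape(-1, nn)
    point_data = {}
    cell_data = {}
    for tag, store in (("PointData", point_data), ("CellData", cell_data)):
        sec = piece.find(tag)
        if sec is None:
            continue
        for el in sec.findall("DataArray"):
            store[el.get("Name")] = parse(el)
    return nodes, elems, point_data, cell_data, meta


def write_vtu_series(results_frames, mesh: TissueMesh, out_dir,
                     basename: str = "frame", meta: dict | None = None,
                     last_valid: int | None = None) -> list:
    """One VTU per frame plus a PVD collection index.

    results_frames: iterable of (t_ms, {array_name: values}).  Returns the
    written paths (index last).  ``last_valid`` marks partial results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    paths = []
    for k, (t, arrays) in enumerate(results_frames):
        p = out_dir / f"{basename}_{k:05d}.vtu"
        write_vtu(p, mesh, point_data=arrays, meta=meta)
        entries.append((t, p.name))
        paths.append(p)
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="Collection" version="0.1">', " <Collection>"]
    for k, (t, name) in enumerate(entries):
        flag = ""
        if last_valid is not None and k > last_valid:
            flag = ' group="invalid"'
        lines.append(f'  <DataSet timestep="{t}" file="{name}"{flag}/>')
    lines += [" </Collection>", "</VTKFile>"]
    index = out_dir / f"{basename}.pvd"
    index.write_text("\n".join(lines))
    paths.append(index)
    return paths


# --- run configuration ---

_CONFIG_SCHEMA = {
    "fixture": str, "preset": str, "remodeling": str, "cv_uniform": float,
    "dt": float, "t_end": float, "bdf_order": int, "store_stride": float,
    "seed": int, "out_dir": str, "protocol": str, "paroxysmal": bool,
}


@dataclass
class RunConfig:
    """Validated, hashable run description (unknown keys rejected)."""

    values: dict

    def __post_init__(self):
        for key, val in self.values.items():
            if key not in _CONFIG_SCHEMA:
                raise ValueError(f"unknown config key {key!r}; known: "
                                 f"{sorted(_CONFIG_SCHEMA)}")
            want = _CONFIG_SCHEMA[key]
            if want is float and isinstance(val, int):
                val = float(val)
            if not isinstance(val, want):
                raise TypeError(f"config key {key!r} must be {want.__name__}")

    @property
    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.values, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({**self.values, "_hash": self.content_hash}, fh, indent=1)


def save_checkpoint(path, result) -> None:
    """Dense state checkpoint: potential frames, final gates/concentrations."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=result.times)
        f.create_dataset("u", data=result.frames)
        f.create_dataset("gates", data=result.state.gates)
        f.create_dataset("concentrations", data=result.state.conc)
        f.attrs["config_hash"] = result.config_hash
        f.attrs["completed"] = result.completed


def load_checkpoint(path) -> dict:
    import h5py

    with h5py.File(path, "r") as f:
        return {"t": f["t"][...], "u": f["u"][...],
                "gates": f["gates"][...],
                "concentrations": f["concentrations"][...],
                "config_hash": f.attrs["config_hash"],
                "completed": bool(f.attrs["completed"])}
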