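"""Minimal ASCII VTU (VTK XML UnstructuredGrid) reader/writer.

Only the subset needed here is supported: triangle meshes, point-data and
cell-data scalar/vector arrays in ascii format, written at full double
precision so that write -> read round-trips to 1e-12 relative.  Boundary
facets and their inlet/outlet/wall tags are carried in FieldData arrays; for
foreign files without them, boundary edges are derived from the triangulation
and tagged by x-extremes (inlet at min x, outlet at max x, wall elsewhere).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .flow import FlowCase, TimePeriodicVelocityField
from .mesh import INLET, OUTLET, WALL, Mesh

_TAG_CODES = {INLET: 0, OUTLET: 1, WALL: 2}
_CODE_TAGS = {v: k for k, v in _TAG_CODES.items()}


def _fmt(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    if flat.dtype.kind in "iu":
        return " ".join(str(int(v)) for v in flat)
    return " ".join(format(float(v), ".17g") for v in flat)


def _data_array(name: str | None, arr: np.ndarray, ncomp: int | None = None) -> ET.Element:
    arr = np.asarray(arr)
    vtype = "Int64" if arr.dtype.kind in "iu" else "Float64"
    el = ET.Element("DataArray", {"type": vtype, "format": "ascii"})
    if name is not None:
        el.set("Name", name)
    if ncomp is None:
        ncomp = arr.shape[1] if arr.ndim > 1 else 1
    el.set("NumberOfComponents", str(ncomp))
    el.text = _fmt(arr)
    return el


def _pad3(vec: np.ndarray) -> np.ndarray:
    """2-component vectors -> 3-component with z = 0 (VTK convention)."""
    if vec.ndim == 2 and vec.shape[1] == 2:
        out = np.zeros((len(vec), 3))
        out[:, :2] = vec
        return out
    return vec


def write_vtu(
    path: str | Path,
    mesh: Mesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a triangle mesh with named point/cell arrays to an ascii .vtu."""
    root = ET.Element(
        "VTKFile", {"type": "UnstructuredGrid", "version": "0.1", "byte_order": "LittleEndian"}
    )
    grid = ET.SubElement(root, "UnstructuredGrid")

    fdata = ET.SubElement(grid, "FieldData")
    fdata.append(_data_array("boundary_facets", mesh.boundary_facets.astype(np.int64)))
    codes = np.array([_TAG_CODES[t] for t in mesh.facet_tags], dtype=np.int64)
    fdata.append(_data_array("facet_tags", codes))

    piece = ET.SubElement(
        grid,
        "Piece",
        {"NumberOfPoints": str(len(mesh.nodes)), "NumberOfCells": str(len(mesh.elements))},
    )
    pts = ET.SubElement(piece, "Points")
    pts.append(_data_array(None, _pad3(mesh.nodes), ncomp=3))
    cells = ET.SubElement(piece, "Cells")
    cells.append(_data_array("connectivity", mesh.elements.astype(np.int64)))
    cells.append(_data_array("offsets", 3 * np.arange(1, len(mesh.elements) + 1, dtype=np.int64)))
    cells.append(_data_array("types", np.full(len(mesh.elements), 5, dtype=np.int64)))

    pd = ET.SubElement(piece, "PointData")
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr, dtype=float)
        if len(arr) != len(mesh.nodes):
            raise ValueError(f"point array {name!r} length does not match node count")
        pd.append(_data_array(name, _pad3(arr)))
    cd = ET.SubElement(piece, "CellData")
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr, dtype=float)
        if len(arr) != len(mesh.elements):
            raise ValueError(f"cell array {name!r} length does not match cell count")
        cd.append(_data_array(name, arr))

    ET.ElementTree(root).write(path, xml_declaration=True)


def _parse_array(el: ET.Element) -> np.ndarray:
    dtype = np.int64 if el.get("type", "").startswith("Int") else np.float64
    tokens = (el.text or "").split()
    vals = np.array(tokens, dtype=np.float64).astype(dtype)
    ncomp = int(el.get("NumberOfComponents", "1"))
    if ncomp > 1:
        vals = vals.reshape(-1, ncomp)
    return vals


def read_vtu(path: str | Path) -> tuple[Mesh, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read an ascii .vtu; returns (mesh, point_data, cell_data).

    3-component vectors with zero third component come back as (N, 2).
    """
    root = ET.parse(path).getroot()
    grid = root.find("UnstructuredGrid")
    if grid is None:
        raise ValueError(f"{path}: not an UnstructuredGrid VTU file")
    piece = grid.find("Piece")
    pts_el = piece.find("Points/DataArray")
    nodes3 = _parse_array(pts_el)
    nodes = nodes3[:, :2]
    conn = offsets = None
    for da in piece.find("Cells"):
        if da.get("Name") == "connectivity":
            conn = _parse_array(da)
        elif da.get("Name") == "offsets":
            offsets = _parse_array(da)
    if conn is None or offsets is None:
        raise ValueError(f"{path}: missing cell connectivity")
    elements = np.asarray(conn).reshape(-1, 3)

    facets = tags = None
    fdata = grid.find("FieldData")
    if fdata is not None:
        for da in fdata:
            if da.get("Name") == "boundary_facets":
                facets = np.asarray(_parse_array(da)).reshape(-1, 2)
            elif da.get("Name") == "facet_tags":
                tags = np.array([_CODE_TAGS[int(c)] for c in np.ravel(_parse_array(da))])
    if facets is None or tags is None:
        facets, tags = _derive_boundary(nodes, elements)

    mesh = Mesh(nodes, elements, facets, tags, kind="external")

    def read_section(section: str, n: int) -> dict[str, np.ndarray]:
        out = {}
        sec = piece.find(section)
        if sec is None:
            return out
        for da in sec:
            arr = _parse_array(da)
            if len(arr) != n:
                raise ValueError(
                    f"{path}: array {da.get('Name')!r} length {len(arr)} "
                    f"does not match count {n}"
                )
            if arr.ndim == 2 and arr.shape[1] == 3 and np.all(arr[:, 2] == 0):
                arr = arr[:, :2]
            out[da.get("Name")] = arr
        return out

    point_data = read_section("PointData", len(nodes))
    cell_data = read_section("CellData", len(elements))
    return mesh, point_data, cell_data


def _derive_boundary(nodes: np.ndarray, elements: np.ndarray):
    edges = np.sort(
        np.concatenate([elements[:, [0, 1]], elements[:, [1, 2]], elements[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    facets = uniq[counts == 1]
    xmin, xmax = nodes[:, 0].min(), nodes[:, 0].max()
    tol = 1e-9 * max(1.0, xmax - xmin)
    tags = []
    for a, b in facets:
        xa, xb = nodes[a, 0], nodes[b, 0]
        if abs(xa - xmin) < tol and abs(xb - xmin) < tol:
            tags.append(INLET)
        elif abs(xa - xmax) < tol and abs(xb - xmax) < tol:
            tags.append(OUTLET)
        else:
            tags.append(WALL)
    return facets, np.array(tags)


def write_field(field: TimePeriodicVelocityField, directory: str | Path) -> None:
    """Write a velocity field series: mesh.vtu, frame_XXXX.vtu, series.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_vtu(directory / "mesh.vtu", field.mesh)
    files = []
    for k, frame in enumerate(field.frames):
        name = f"frame_{k:04d}.vtu"
        write_vtu(directory / name, field.mesh, point_data={"velocity": frame})
        files.append(name)
    meta = {
        "period": field.period,
        "frame_times": [float(t) for t in field.frame_times],
        "files": files,
    }
    (directory / "series.json").write_text(json.dumps(meta, indent=1))


def read_field_series(
    mesh_file: str | Path,
    field_files: list[str | Path],
    period: float,
    frame_times: np.ndarray | None = None,
    viscosity: float = 0.04,
    label: str = "external",
) -> FlowCase:
    """Assemble a FlowCase from a mesh file and per-frame velocity files.

    Every frame file must carry a point vector array named "velocity" on the
    same number of nodes as the mesh.
    """
    mesh, _, _ = read_vtu(mesh_file)
    mesh.validate()
    frames = []
    for f in field_files:
        _, pdata, _ = read_vtu(f)
        if "velocity" not in pdata:
            raise ValueError(f"{f}: no point array named 'velocity'")
        vel = pdata["velocity"]
        if len(vel) != len(mesh.nodes):
            raise ValueError(
                f"{f}: velocity node count {len(vel)} does not match mesh "
                f"({len(mesh.nodes)})"
            )
        frames.append(vel)
    frames = np.asarray(frames)
    if frame_times is None:
        frame_times = np.arange(len(frames)) * period / len(frames)
    field = TimePeriodicVelocityField(mesh, frames, period, np.asarray(frame_times, float))
    return FlowCase(mesh, field, period, viscosity=viscosity, label=label)


def read_field_series_dir(directory: str | Path, viscosity: float = 0.04) -> FlowCase:
    """Read a series written by :func:`write_field`."""
    directory = Path(directory)
    meta = json.loads((directory / "series.json").read_text())
    return read_field_series(
        directory / "mesh.vtu",
        [directory / f for f in meta["files"]],
        period=meta["period"],
        frame_times=np.asarray(meta["frame_times"]),
        viscosity=viscosity,
    )
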