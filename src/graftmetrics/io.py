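"""Mesh and field I/O.

Canonical on-disk dialect is ASCII VTK XML (``.vtu`` unstructured grids,
``.vtp`` polydata); legacy ASCII VTK (``.vtk``) and XDMF+HDF5 (``.xdmf``)
are read-compatible imports, STL is geometry-only import.  Floats are
written with 17 significant digits so write→read round-trips are lossless.

A time series is a list of per-step files plus the sample times; the
convenience manifest is a CSV with columns ``time,path``.
"""

from __future__ import annotations

import os
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Centreline,
    CycleWindow,
    FieldSeries,
    MetricMap,
    SurfaceMesh,
    VolumeMesh,
)

_VTK_TRIANGLE = 5
_VTK_TETRA = 10

_KIND_BY_NCOMP = {1: "scalar", 3: "vector3", 6: "sym_tensor3"}


def _fmt_array(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.dtype.kind == "f":
        return " ".join(f"{x:.17g}" for x in a.ravel())
    return " ".join(str(int(x)) for x in a.ravel())


def _data_array(name: str | None, a: np.ndarray, ncomp: int | None = None) -> ET.Element:
    a = np.asarray(a)
    vtype = "Float64" if a.dtype.kind == "f" else "Int64"
    el = ET.Element("DataArray", {"type": vtype, "format": "ascii"})
    if name is not None:
        el.set("Name", name)
    if ncomp is not None:
        el.set("NumberOfComponents", str(ncomp))
    el.text = _fmt_array(a)
    return el


def _parse_data_array(el: ET.Element) -> np.ndarray:
    if el.get("format", "ascii") != "ascii":
        raise ValueError("only ascii-format VTK XML DataArrays are supported")
    text = el.text or ""
    dtype = float if el.get("type", "Float64").startswith("Float") else np.int64
    a = np.array(text.split(), dtype=dtype)
    ncomp = int(el.get("NumberOfComponents", "1"))
    if ncomp > 1:
        a = a.reshape(-1, ncomp)
    return a


# ---------------------------------------------------------------------------
# VTK XML write / read


def write_vtk_xml(
    path: str | Path,
    points: np.ndarray,
    cells: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write an ASCII ``.vtp`` (triangles) or ``.vtu`` (triangles or tets).

    Data arrays may be (n,), (n, 3) or (n, 6).
    """
    path = Path(path)
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    npercell = cells.shape[1]
    is_vtp = path.suffix == ".vtp"
    if is_vtp and npercell != 3:
        raise ValueError(".vtp files hold triangle surfaces only")

    root = ET.Element(
        "VTKFile",
        {
            "type": "PolyData" if is_vtp else "UnstructuredGrid",
            "version": "0.1",
            "byte_order": "LittleEndian",
        },
    )
    grid = ET.SubElement(root, "PolyData" if is_vtp else "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", {"NumberOfPoints": str(len(points))})
    if is_vtp:
        piece.set("NumberOfPolys", str(len(cells)))
    else:
        piece.set("NumberOfCells", str(len(cells)))

    pts = ET.SubElement(piece, "Points")
    pts.append(_data_array(None, points, 3))

    offsets = np.arange(1, len(cells) + 1, dtype=np.int64) * npercell
    if is_vtp:
        conn = ET.SubElement(piece, "Polys")
    else:
        conn = ET.SubElement(piece, "Cells")
    conn.append(_data_array("connectivity", cells.ravel()))
    conn.append(_data_array("offsets", offsets))
    if not is_vtp:
        ctype = _VTK_TRIANGLE if npercell == 3 else _VTK_TETRA
        conn.append(_data_array("types", np.full(len(cells), ctype, dtype=np.int64)))

    for tag, data, n in (("PointData", point_data, len(points)), ("CellData", cell_data, len(cells))):
        if not data:
            continue
        sec = ET.SubElement(piece, tag)
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) != n:
                raise ValueError(
                    f"array {name!r} has length {len(arr)}, expected {n} for {tag}"
                )
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            sec.append(_data_array(name, arr, ncomp if ncomp > 1 else None))

    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="ascii")


def read_vtk_xml(path: str | Path):
    """Read an ASCII ``.vtu``/``.vtp`` file.

    Returns ``(points, cells, point_data, cell_data)`` where ``cells`` is an
    (m, 3) or (m, 4) integer array.
    """
    root = ET.parse(path).getroot()
    grid = root.find("PolyData")
    if grid is None:
        grid = root.find("UnstructuredGrid")
    if grid is None:
        raise ValueError(f"{path}: not a PolyData/UnstructuredGrid VTK XML file")
    piece = grid.find("Piece")
    points = _parse_data_array(piece.find("Points/DataArray")).reshape(-1, 3)

    cell_sec = piece.find("Polys") if grid.tag == "PolyData" else piece.find("Cells")
    arrays = {el.get("Name"): _parse_data_array(el) for el in cell_sec.findall("DataArray")}
    connectivity = np.asarray(arrays["connectivity"], dtype=np.int64).ravel()
    offsets = np.asarray(arrays["offsets"], dtype=np.int64).ravel()
    sizes = np.diff(np.concatenate([[0], offsets]))
    if len(sizes) and not np.all(sizes == sizes[0]):
        raise ValueError(f"{path}: mixed cell sizes are not supported")
    npercell = int(sizes[0]) if len(sizes) else 3
    cells = connectivity.reshape(-1, npercell)

    def _section(tag):
        sec = piece.find(tag)
        if sec is None:
            return {}
        return {el.get("Name"): _parse_data_array(el) for el in sec.findall("DataArray")}

    return points, cells, _section("PointData"), _section("CellData")


# ---------------------------------------------------------------------------
# Legacy VTK (ASCII) read


def read_vtk_legacy(path: str | Path):
    """Read a classic ASCII ``.vtk`` file (POLYDATA or UNSTRUCTURED_GRID).

    Supports POINTS, POLYGONS / CELLS+CELL_TYPES, and SCALARS / VECTORS /
    FIELD arrays under POINT_DATA / CELL_DATA.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(n=1):
        nonlocal pos
        out = tokens[pos : pos + n]
        pos += n
        return out

    points = cells = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    target = None
    target_n = 0

    def read_floats(n):
        return np.array(take(n), dtype=float)

    while pos < len(tokens):
        tok = take()[0].upper()
        if tok == "POINTS":
            n = int(take()[0])
            take()  # dtype
            points = read_floats(3 * n).reshape(n, 3)
        elif tok in ("POLYGONS", "CELLS"):
            n, size = int(take()[0]), int(take()[0])
            raw = np.array(take(size), dtype=np.int64)
            out, i = [], 0
            for _ in range(n):
                k = raw[i]
                out.append(raw[i + 1 : i + 1 + k])
                i += k + 1
            sizes = {len(c) for c in out}
            if len(sizes) != 1:
                raise ValueError("mixed cell sizes in legacy VTK file")
            cells = np.vstack(out)
        elif tok == "CELL_TYPES":
            n = int(take()[0])
            take(n)
        elif tok == "POINT_DATA":
            target, target_n = point_data, int(take()[0])
        elif tok == "CELL_DATA":
            target, target_n = cell_data, int(take()[0])
        elif tok == "SCALARS":
            name = take()[0]
            take()  # dtype (+ optional numComp handled below)
            ncomp = 1
            if peek() and peek().isdigit():
                ncomp = int(take()[0])
            if peek() and peek().upper() == "LOOKUP_TABLE":
                take(2)
            a = read_floats(target_n * ncomp)
            target[name] = a if ncomp == 1 else a.reshape(target_n, ncomp)
        elif tok == "VECTORS":
            name = take()[0]
            take()  # dtype
            target[name] = read_floats(3 * target_n).reshape(target_n, 3)
        elif tok == "FIELD":
            take()  # field name
            narr = int(take()[0])
            for _ in range(narr):
                name, ncomp, ntup = take()[0], int(take()[0]), int(take()[0])
                take()  # dtype
                a = read_floats(ncomp * ntup)
                target[name] = a if ncomp == 1 else a.reshape(ntup, ncomp)
        # other keywords (DATASET, header words, LINES...) are skipped

    if points is None or cells is None:
        raise ValueError(f"{path}: no POINTS/cells found in legacy VTK file")
    return points, cells, point_data, cell_data


# ---------------------------------------------------------------------------
# XDMF + HDF5 read


def read_xdmf(path: str | Path):
    """Read the first grid of an XDMF file; HDF5 heavy data resolved via h5py.

    Supports Triangle / Tetrahedron topologies, XYZ geometry and Node/Cell
    attributes with Format="HDF" or inline XML DataItems.
    """
    import h5py

    path = Path(path)
    root = ET.parse(path).getroot()
    grid = root.find(".//Grid[Topology]")
    if grid is None:
        raise ValueError(f"{path}: no Grid with a Topology found")

    def load_item(item: ET.Element) -> np.ndarray:
        fmt = item.get("Format", "XML")
        dims = [int(d) for d in item.get("Dimensions", "").split()]
        if fmt.upper() == "HDF":
            ref = (item.text or "").strip()
            fname, dset = ref.split(":", 1)
            with h5py.File(path.parent / fname, "r") as h5:
                a = np.asarray(h5[dset])
        else:
            a = np.array((item.text or "").split(), dtype=float)
        return a.reshape(dims) if dims else a

    topo = grid.find("Topology")
    cells = np.asarray(load_item(topo.find("DataItem")), dtype=np.int64)
    ttype = (topo.get("TopologyType") or topo.get("Type") or "").lower()
    npercell = 3 if "tri" in ttype else 4
    cells = cells.reshape(-1, npercell)

    geom = grid.find("Geometry")
    points = np.asarray(load_item(geom.find("DataItem")), dtype=float).reshape(-1, 3)

    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    for attr in grid.findall("Attribute"):
        name = attr.get("Name")
        center = (attr.get("Center") or "Node").lower()
        a = load_item(attr.find("DataItem"))
        (point_data if center == "node" else cell_data)[name] = np.asarray(a, dtype=float)
    return points, cells, point_data, cell_data


def read_stl(path: str | Path) -> SurfaceMesh:
    """Geometry-only STL import (via trimesh)."""
    import trimesh

    tm = trimesh.load_mesh(str(path))
    return SurfaceMesh(points=np.asarray(tm.vertices), triangles=np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# Dispatch and series-level API


def read_mesh_and_data(path: str | Path):
    """Read any supported file into (points, cells, point_data, cell_data)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".vtu", ".vtp"):
        return read_vtk_xml(path)
    if suffix == ".vtk":
        return read_vtk_legacy(path)
    if suffix == ".xdmf":
        return read_xdmf(path)
    raise ValueError(f"unsupported mesh file format: {path}")


def _mesh_from(points, cells):
    if cells.shape[1] == 3:
        return SurfaceMesh(points=points, triangles=cells)
    return VolumeMesh(points=points, tets=cells)


def read_field_series(
    paths: list[str | Path],
    time_values: list[float],
    attachment: str,
    field_name: str,
    to_elements: bool = False,
):
    """Read a per-step file series into a mesh plus :class:`FieldSeries`.

    All steps must share an identical mesh topology; ``time_values`` become
    the cycle sample times.  With ``to_elements=True`` a node-attached field
    is averaged onto elements after loading.
    """
    from .core import node_to_element

    if len(paths) != len(time_values):
        raise ValueError("paths and time_values must have equal length")
    if attachment not in ("node", "element"):
        raise ValueError("attachment must be 'node' or 'element'")

    mesh = None
    ref_points = ref_cells = None
    samples = []
    for step, p in enumerate(paths):
        points, cells, point_data, cell_data = read_mesh_and_data(p)
        if mesh is None:
            ref_points, ref_cells = points, cells
            mesh = _mesh_from(points, cells)
        else:
            if cells.shape != ref_cells.shape or not np.array_equal(cells, ref_cells):
                raise ValueError(
                    f"topology mismatch at step {step} ({p}): connectivity differs from step 0"
                )
            if points.shape != ref_points.shape:
                raise ValueError(
                    f"topology mismatch at step {step} ({p}): point count differs from step 0"
                )
        data = point_data if attachment == "node" else cell_data
        if field_name not in data:
            raise KeyError(
                f"field {field_name!r} not in {p} ({attachment} data); "
                f"available: {sorted(data)}"
            )
        samples.append(np.atleast_2d(np.asarray(data[field_name], dtype=float).T).T)

    vals = np.stack(samples)
    if vals.ndim == 2:
        vals = vals[:, :, None]
    kind = _KIND_BY_NCOMP.get(vals.shape[2])
    if kind is None:
        raise ValueError(f"unsupported component count {vals.shape[2]} for {field_name!r}")
    t = np.asarray(time_values, dtype=float)
    window = CycleWindow(t_start=t[0], period_T=t[-1] - t[0], sample_times=t)
    series = FieldSeries(kind=kind, attachment=attachment, values=vals, units="", window=window)
    if to_elements and attachment == "node":
        series = node_to_element(series, mesh)
    return mesh, series


def write_metric_map(
    mesh: SurfaceMesh,
    maps: list[MetricMap] | dict[str, np.ndarray],
    path: str | Path,
) -> None:
    """Write per-element metric maps as cell data of a ``.vtp``/``.vtu`` file."""
    if isinstance(maps, dict):
        cell_data = {k: np.asarray(v, dtype=float) for k, v in maps.items()}
    else:
        cell_data = {m.metric_name: m.values for m in maps}
    for name, arr in cell_data.items():
        if len(arr) != mesh.n_elements:
            raise ValueError(
                f"map {name!r} has {len(arr)} values for {mesh.n_elements} elements"
            )
        if np.any(~np.isfinite(arr)):
            warnings.warn(f"map {name!r} contains non-finite values; written verbatim")
    write_vtk_xml(path, mesh.points, mesh.triangles, cell_data=cell_data)


def read_metric_maps(path: str | Path):
    """Inverse of :func:`write_metric_map`: returns (mesh, {name: values})."""
    points, cells, _, cell_data = read_mesh_and_data(path)
    return _mesh_from(points, cells), cell_data


# ---------------------------------------------------------------------------
# Manifests and centrelines


def write_series_manifest(path: str | Path, times, files) -> None:
    """CSV manifest for a field series: columns ``time,path`` (paths relative)."""
    pd.DataFrame({"time": np.asarray(times, dtype=float), "path": list(map(str, files))}).to_csv(
        path, index=False
    )


def read_series_manifest(path: str | Path):
    """Returns (times, absolute paths) from a series manifest CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    paths = [
        p if os.path.isabs(p) else str(path.parent / p) for p in df["path"].astype(str)
    ]
    return df["time"].to_numpy(dtype=float), paths


def write_centreline_csv(path: str | Path, centreline: Centreline) -> None:
    """Centreline as x,y,z rows plus an optional landmark name per row."""
    df = pd.DataFrame(centreline.points, columns=["x", "y", "z"])
    names = [""] * len(df)
    for name, s in centreline.landmarks.items():
        i = int(np.argmin(np.abs(centreline.arclength - s)))
        names[i] = name
    df["landmark"] = names
    df.to_csv(path, index=False)


def read_centreline_csv(path: str | Path) -> Centreline:
    df = pd.read_csv(path)
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    cl = Centreline(points=pts)
    if "landmark" in df.columns:
        marks = {}
        for i, name in enumerate(df["landmark"].fillna("")):
            if str(name).strip():
                marks[str(name).strip()] = float(cl.arclength[i])
        cl.landmarks.update(marks)
    return cl
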