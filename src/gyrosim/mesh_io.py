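"""Reading and writing tetrahedral volume meshes and triangulated surfaces.

Volume formats: Gmsh ASCII (.msh, v2.2 written, v2.2/v4.1 read), VTK legacy
ASCII (.vtk), and ASCII VTU (.vtu).  Surface formats (PLY/OBJ/STL/OFF) are
delegated to trimesh.  Readers validate element orientation and report parse
failures with the offending line number.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import trimesh

from .geometry import TetMesh, extract_boundary

__all__ = [
    "MeshParseError",
    "read_mesh",
    "write_mesh",
    "read_surface",
    "write_surface",
]

_VOLUME_EXT = {".msh", ".vtk", ".vtu"}
_SURFACE_EXT = {".ply", ".obj", ".stl", ".off"}


class MeshParseError(ValueError):
    """Malformed mesh file; carries the 1-based line number where known."""

    def __init__(self, msg: str, line: int | None = None):
        self.line = line
        super().__init__(msg if line is None else f"line {line}: {msg}")


def _format_of(path: Path, fmt: str | None) -> str:
    ext = ("." + fmt.lower().lstrip(".")) if fmt else path.suffix.lower()
    return ext


def _validate_tets(nodes: np.ndarray, tets: np.ndarray) -> TetMesh:
    if tets.size == 0:
        raise MeshParseError("file contains no tetrahedra")
    if tets.min() < 0 or tets.max() >= len(nodes):
        raise MeshParseError("tetrahedron references a node index out of range")
    mesh = TetMesh(nodes, tets, extract_boundary(tets))
    vols = mesh.tet_volumes()
    if vols.min() <= 0:
        bad = int(np.argmin(vols))
        raise MeshParseError(
            f"tetrahedron {bad} has non-positive volume {vols[bad]:.3e}"
        )
    return mesh


def read_mesh(path, fmt: str | None = None) -> TetMesh:
    """Read a tetrahedral mesh (.msh, .vtk, .vtu)."""
    path = Path(path)
    ext = _format_of(path, fmt)
    if ext == ".msh":
        return _read_msh(path)
    if ext == ".vtk":
        return _read_vtk(path)
    if ext == ".vtu":
        return _read_vtu(path)
    raise ValueError(f"unsupported volume mesh format '{ext}' (use .msh/.vtk/.vtu)")


def write_mesh(mesh: TetMesh, path, fmt: str | None = None, cell_data: dict | None = None) -> None:
    """Write a tetrahedral mesh; ``cell_data`` maps names to per-tet scalars."""
    path = Path(path)
    ext = _format_of(path, fmt)
    if ext == ".msh":
        _write_msh(mesh, path)
    elif ext == ".vtk":
        _write_vtk(mesh, path)
    elif ext == ".vtu":
        _write_vtu(mesh, path, cell_data or {})
    else:
        raise ValueError(f"unsupported volume mesh format '{ext}' (use .msh/.vtk/.vtu)")


def read_surface(path) -> trimesh.Trimesh:
    """Read a triangulated surface (PLY/OBJ/STL/OFF) via trimesh."""
    path = Path(path)
    if path.suffix.lower() not in _SURFACE_EXT:
        raise ValueError(f"unsupported surface format '{path.suffix}'")
    mesh = trimesh.load(str(path), process=False, force="mesh")
    return mesh


def write_surface(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _SURFACE_EXT:
        raise ValueError(f"unsupported surface format '{path.suffix}'")
    trimesh.Trimesh(vertices=vertices, faces=faces, process=False).export(str(path))


# ---------------------------------------------------------------------------
# Gmsh ASCII
# ---------------------------------------------------------------------------

# Gmsh element types we understand; everything else is an error
_GMSH_TET = 4
_GMSH_TRI = 2
_GMSH_NODE_COUNT = {1: 2, 2: 3, 4: 4, 15: 1}


def _write_msh(mesh: TetMesh, path: Path) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}")
    lines += ["$EndNodes", "$Elements", str(mesh.n_tets)]
    for i, t in enumerate(mesh.tets, start=1):
        lines.append(f"{i} 4 2 0 1 {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}")
    lines += ["$EndElements", ""]
    path.write_text("\n".join(lines))


def _read_msh(path: Path) -> TetMesh:
    lines = path.read_text().splitlines()
    i = 0

    def expect(section):
        nonlocal i
        while i < len(lines) and lines[i].strip() != section:
            i += 1
        if i >= len(lines):
            raise MeshParseError(f"missing {section} section", line=len(lines))
        i += 1

    expect("$MeshFormat")
    try:
        version = float(lines[i].split()[0])
    except (ValueError, IndexError):
        raise MeshParseError("unreadable $MeshFormat header", line=i + 1)
    if lines[i].split()[1] != "0":
        raise MeshParseError("binary .msh files are not supported", line=i + 1)
    if version >= 4.0:
        return _read_msh41(lines, i)
    return _read_msh22(lines, i)


def _read_msh22(lines: list, i: int) -> TetMesh:
    def find(section, start):
        j = start
        while j < len(lines) and lines[j].strip() != section:
            j += 1
        if j >= len(lines):
            raise MeshParseError(f"missing {section} section", line=len(lines))
        return j + 1

    i = find("$Nodes", i)
    try:
        n_nodes = int(lines[i])
    except ValueError:
        raise MeshParseError("expected node count", line=i + 1)
    coords = {}
    for j in range(i + 1, i + 1 + n_nodes):
        parts = lines[j].split()
        try:
            coords[int(parts[0])] = [float(x) for x in parts[1:4]]
        except (ValueError, IndexError):
            raise MeshParseError("malformed node record", line=j + 1)
    i = find("$Elements", i + n_nodes)
    try:
        n_elem = int(lines[i])
    except ValueError:
        raise MeshParseError("expected element count", line=i + 1)
    tets = []
    unsupported = set()
    for j in range(i + 1, i + 1 + n_elem):
        parts = lines[j].split()
        try:
            etype = int(parts[1])
            n_tags = int(parts[2])
            conn = [int(x) for x in parts[3 + n_tags :]]
        except (ValueError, IndexError):
            raise MeshParseError("malformed element record", line=j + 1)
        if etype == _GMSH_TET:
            tets.append(conn)
        elif etype in (_GMSH_TRI, 1, 15):
            continue  # surface/edge/point elements accompany volume meshes
        else:
            unsupported.add(etype)
    if unsupported:
        raise MeshParseError(
            "unsupported element types in .msh file: "
            + ", ".join(str(t) for t in sorted(unsupported))
        )
    tags = sorted(coords)
    remap = {t: k for k, t in enumerate(tags)}
    nodes = np.array([coords[t] for t in tags])
    tets_arr = np.array([[remap[v] for v in t] for t in tets], dtype=np.int64)
    return _validate_tets(nodes, tets_arr)


def _read_msh41(lines: list, i: int) -> TetMesh:
    def find(section, start):
        j = start
        while j < len(lines) and lines[j].strip() != section:
            j += 1
        if j >= len(lines):
            raise MeshParseError(f"missing {section} section", line=len(lines))
        return j + 1

    i = find("$Nodes", i)
    header = lines[i].split()
    n_blocks = int(header[0])
    i += 1
    coords = {}
    for _ in range(n_blocks):
        parts = lines[i].split()
        n_in_block = int(parts[3])
        i += 1
        tags = [int(lines[i + k]) for k in range(n_in_block)]
        i += n_in_block
        for k in range(n_in_block):
            xyz = lines[i + k].split()
            coords[tags[k]] = [float(x) for x in xyz[:3]]
        i += n_in_block
    i = find("$Elements", i)
    header = lines[i].split()
    n_blocks = int(header[0])
    i += 1
    tets = []
    unsupported = set()
    for _ in range(n_blocks):
        parts = lines[i].split()
        etype = int(parts[2])
        n_in_block = int(parts[3])
        i += 1
        for k in range(n_in_block):
            conn = [int(x) for x in lines[i + k].split()[1:]]
            if etype == _GMSH_TET:
                tets.append(conn)
            elif etype in (_GMSH_TRI, 1, 15):
                pass
            else:
                unsupported.add(etype)
        i += n_in_block
    if unsupported:
        raise MeshParseError(
            "unsupported element types in .msh file: "
            + ", ".join(str(t) for t in sorted(unsupported))
        )
    tags = sorted(coords)
    remap = {t: k for k, t in enumerate(tags)}
    nodes = np.array([coords[t] for t in tags])
    tets_arr = np.array([[remap[v] for v in t] for t in tets], dtype=np.int64)
    return _validate_tets(nodes, tets_arr)


# ---------------------------------------------------------------------------
# VTK legacy ASCII
# ---------------------------------------------------------------------------

_VTK_TET = 10


def _write_vtk(mesh: TetMesh, path: Path) -> None:
    out = [
        "# vtk DataFile Version 3.0",
        "gyrosim mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    out += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in mesh.nodes]
    out.append(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}")
    out += [f"4 {t[0]} {t[1]} {t[2]} {t[3]}" for t in mesh.tets]
    out.append(f"CELL_TYPES {mesh.n_tets}")
    out += ["10"] * mesh.n_tets
    out.append("")
    path.write_text("\n".join(out))


def _read_vtk(path: Path) -> TetMesh:
    lines = path.read_text().splitlines()
    if len(lines) < 5 or "vtk" not in lines[0].lower():
        raise MeshParseError("not a VTK legacy file", line=1)
    if lines[2].strip().upper() != "ASCII":
        raise MeshParseError("only ASCII VTK files are supported", line=3)
    i = 0
    while i < len(lines) and not lines[i].upper().startswith("POINTS"):
        i += 1
    if i == len(lines):
        raise MeshParseError("missing POINTS section", line=len(lines))
    n_pts = int(lines[i].split()[1])
    vals: list = []
    j = i + 1
    while len(vals) < 3 * n_pts:
        if j >= len(lines):
            raise MeshParseError("truncated POINTS section", line=j)
        try:
            vals.extend(float(x) for x in lines[j].split())
        except ValueError:
            raise MeshParseError("malformed POINTS data", line=j + 1)
        j += 1
    nodes = np.array(vals[: 3 * n_pts]).reshape(-1, 3)
    while j < len(lines) and not lines[j].upper().startswith("CELLS"):
        j += 1
    if j == len(lines):
        raise MeshParseError("missing CELLS section", line=len(lines))
    n_cells = int(lines[j].split()[1])
    ints: list = []
    k = j + 1
    while k < len(lines) and not lines[k].upper().startswith("CELL_TYPES"):
        try:
            ints.extend(int(x) for x in lines[k].split())
        except ValueError:
            raise MeshParseError("malformed CELLS data", line=k + 1)
        k += 1
    if k == len(lines):
        raise MeshParseError("missing CELL_TYPES section", line=len(lines))
    types: list = []
    m = k + 1
    while m < len(lines) and len(types) < n_cells:
        types.extend(int(x) for x in lines[m].split())
        m += 1
    cells = []
    pos = 0
    for _ in range(n_cells):
        n = ints[pos]
        cells.append(ints[pos + 1 : pos + 1 + n])
        pos += 1 + n
    bad_types = {t for t in types if t != _VTK_TET}
    if bad_types:
        raise MeshParseError(
            "unsupported VTK cell types: " + ", ".join(str(t) for t in sorted(bad_types))
        )
    tets = np.array(cells, dtype=np.int64)
    return _validate_tets(nodes, tets)


# ---------------------------------------------------------------------------
# VTU (ASCII XML)
# ---------------------------------------------------------------------------


def _write_vtu(mesh: TetMesh, path: Path, cell_data: dict) -> None:
    def arr(a, per_line=1):
        a = np.asarray(a)
        if a.ndim == 1:
            return "\n".join(f"{x:.17g}" if a.dtype.kind == "f" else str(int(x)) for x in a)
        return "\n".join(" ".join(f"{x:.17g}" if a.dtype.kind == "f" else str(int(x)) for x in row) for row in a)

    cd = ""
    if cell_data:
        parts = []
        for name, values in cell_data.items():
            parts.append(
                f'<DataArray type="Float64" Name="{name}" format="ascii">\n'
                + arr(np.asarray(values, dtype=float))
                + "\n</DataArray>"
            )
        cd = "<CellData>\n" + "\n".join(parts) + "\n</CellData>\n"
    xml = (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "<UnstructuredGrid>\n"
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_tets}">\n'
        "<Points>\n"
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">\n'
        + arr(mesh.nodes)
        + "\n</DataArray>\n</Points>\n"
        + cd
        + "<Cells>\n"
        '<DataArray type="Int64" Name="connectivity" format="ascii">\n'
        + arr(mesh.tets)
        + "\n</DataArray>\n"
        '<DataArray type="Int64" Name="offsets" format="ascii">\n'
        + arr(4 * np.arange(1, mesh.n_tets + 1))
        + "\n</DataArray>\n"
        '<DataArray type="UInt8" Name="types" format="ascii">\n'
        + arr(np.full(mesh.n_tets, _VTK_TET))
        + "\n</DataArray>\n"
        "</Cells>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n"
    )
    path.write_text(xml)


def _parse_floats(text: str) -> np.ndarray:
    return np.array(text.split(), dtype=float)


def _read_vtu(path: Path) -> TetMesh:
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as e:
        raise MeshParseError(f"invalid XML: {e.msg}", line=e.position[0]) from e
    root = tree.getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshParseError("no <Piece> element in VTU file")
    arrays = {}
    for da in piece.iter("DataArray"):
        fmt = da.get("format", "ascii")
        if fmt != "ascii":
            raise MeshParseError(f"unsupported VTU DataArray format '{fmt}'")
        arrays[da.get("Name") or "points"] = da
    pts_da = piece.find("./Points/DataArray")
    if pts_da is None:
        raise MeshParseError("missing Points array in VTU file")
    nodes = _parse_floats(pts_da.text).reshape(-1, 3)
    try:
        conn = _parse_floats(arrays["connectivity"].text).astype(np.int64)
        offsets = _parse_floats(arrays["offsets"].text).astype(np.int64)
        types = _parse_floats(arrays["types"].text).astype(np.int64)
    except KeyError as e:
        raise MeshParseError(f"missing Cells array {e} in VTU file") from e
    bad = {int(t) for t in np.unique(types) if t != _VTK_TET}
    if bad:
        raise MeshParseError(
            "unsupported VTU cell types: " + ", ".join(str(t) for t in sorted(bad))
        )
    if not np.all(np.diff(np.concatenate([[0], offsets])) == 4):
        raise MeshParseError("non-tetrahedral connectivity offsets in VTU file")
    tets = conn.reshape(-1, 4)
    return _validate_tets(nodes, tets)
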