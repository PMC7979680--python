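"""Legacy ASCII VTK I/O for hexahedral meshes and fiber polylines.

Covers exactly the two flavours this package exchanges with mesh and
visualization tools: UNSTRUCTURED_GRID files holding VTK_HEXAHEDRON (type
12) cells with optional integer/float cell data, and POLYDATA files
holding polylines with per-line scalar data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .hexmesh import HexMesh

VTK_HEXAHEDRON = 12

__all__ = ["read_hex_vtk", "write_hex_vtk", "write_polylines_vtk", "read_polylines_vtk"]


def write_hex_vtk(
    mesh: HexMesh,
    path: str | Path,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a hex mesh as legacy ASCII VTK; part_id always goes out as
    cell data, plus any extra per-element arrays (e.g. scaled Jacobian)."""
    cell_data = dict(cell_data or {})
    cell_data.setdefault("part_id", mesh.part_id)
    lines = [
        "# vtk DataFile Version 3.0",
        "morphhead hexahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in row) for row in mesh.nodes]
    m = mesh.n_elements
    lines.append(f"CELLS {m} {m * 9}")
    lines += ["8 " + " ".join(str(i) for i in el) for el in mesh.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += [str(VTK_HEXAHEDRON)] * m
    lines.append(f"CELL_DATA {m}")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            lines.append(f"SCALARS {name} int 1")
            lines.append("LOOKUP_TABLE default")
            lines += [str(int(v)) for v in arr]
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{float(v):.10g}" for v in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def _tokens(path: Path):
    for line in path.read_text().splitlines():
        yield from line.split()


def read_hex_vtk(path: str | Path) -> tuple[HexMesh, dict[str, np.ndarray]]:
    """Read a legacy ASCII VTK unstructured grid of hexahedra.

    Returns the mesh and a dict of cell-data arrays (part_id, if present,
    is also installed on the mesh).
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if len(text) < 4 or "ASCII" not in text[2].upper():
        raise ValueError(f"{path}: not a legacy ASCII VTK file")
    tok = _tokens(path)
    nodes = elements = None
    cell_data: dict[str, np.ndarray] = {}
    n_cells = 0
    for t in tok:
        up = t.upper()
        if up == "POINTS":
            n = int(next(tok))
            next(tok)  # dtype
            flat = np.fromiter((float(next(tok)) for _ in range(3 * n)), float, 3 * n)
            nodes = flat.reshape(n, 3)
        elif up == "CELLS":
            n_cells = int(next(tok))
            total = int(next(tok))
            flat = np.fromiter((int(next(tok)) for _ in range(total)), np.int64, total)
            rows = []
            i = 0
            while i < len(flat):
                cnt = int(flat[i])
                if cnt != 8:
                    raise ValueError(f"{path}: non-hexahedral cell with {cnt} nodes")
                rows.append(flat[i + 1 : i + 9])
                i += cnt + 1
            elements = np.array(rows, dtype=np.int64)
        elif up == "CELL_TYPES":
            n = int(next(tok))
            types = [int(next(tok)) for _ in range(n)]
            if any(ct != VTK_HEXAHEDRON for ct in types):
                raise ValueError(f"{path}: contains non-hexahedron cell types")
        elif up == "SCALARS":
            name = next(tok)
            dtype = next(tok).lower()
            next(tok)  # n components
            lut = next(tok)  # LOOKUP_TABLE
            if lut.upper() == "LOOKUP_TABLE":
                next(tok)  # table name
            vals = [next(tok) for _ in range(n_cells)]
            cell_data[name] = (
                np.array(vals, dtype=np.int64)
                if dtype in ("int", "long", "short")
                else np.array(vals, dtype=float)
            )
    if nodes is None or elements is None:
        raise ValueError(f"{path}: missing POINTS or CELLS section")
    part = cell_data.get("part_id")
    return HexMesh(nodes, elements, part), cell_data


def write_polylines_vtk(
    polylines: list[np.ndarray],
    path: str | Path,
    line_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write polylines (list of (k,3) point arrays) as VTK POLYDATA with
    optional per-line scalars (e.g. mean FA)."""
    n_pts = sum(len(p) for p in polylines)
    lines = [
        "# vtk DataFile Version 3.0",
        "morphhead fiber tracts",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n_pts} double",
    ]
    for poly in polylines:
        lines += [" ".join(f"{v:.10g}" for v in row) for row in np.asarray(poly)]
    size = sum(len(p) + 1 for p in polylines)
    lines.append(f"LINES {len(polylines)} {size}")
    offset = 0
    for poly in polylines:
        ids = range(offset, offset + len(poly))
        lines.append(f"{len(poly)} " + " ".join(map(str, ids)))
        offset += len(poly)
    if line_data:
        lines.append(f"CELL_DATA {len(polylines)}")
        for name, arr in line_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{float(v):.10g}" for v in np.asarray(arr)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_polylines_vtk(path: str | Path) -> list[np.ndarray]:
    """Read polylines back from a VTK POLYDATA file."""
    tok = _tokens(Path(path))
    points = None
    polylines: list[np.ndarray] = []
    for t in tok:
        up = t.upper()
        if up == "POINTS":
            n = int(next(tok))
            next(tok)
            flat = np.fromiter((float(next(tok)) for _ in range(3 * n)), float, 3 * n)
            points = flat.reshape(n, 3)
        elif up == "LINES":
            n_lines = int(next(tok))
            next(tok)  # total size
            for _ in range(n_lines):
                k = int(next(tok))
                ids = [int(next(tok)) for _ in range(k)]
                polylines.append(points[ids])  # type: ignore[index]
    return polylines
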