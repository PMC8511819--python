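"""Minimal VTK XML unstructured-grid (.vtu) writer for tet meshes.

ASCII output, sufficient for ParaView/VTK inspection of meshes with
per-element (cell) and per-node (point) data arrays.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshmat import TetMesh

_VTK_TET4 = 10
_VTK_TET10 = 24


def _fmt(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    if flat.dtype.kind in "iu":
        return " ".join(str(int(v)) for v in flat)
    return " ".join(format(float(v), ".9g") for v in flat)


def write_vtu(
    mesh: TetMesh,
    path,
    cell_data: dict | None = None,
    point_data: dict | None = None,
) -> Path:
    """Write the mesh with optional data arrays to an ASCII .vtu file."""
    path = Path(path)
    npe = mesh.elements.shape[1]
    ctype = _VTK_TET4 if npe == 4 else _VTK_TET10
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    cell_data = dict(cell_data or {})
    cell_data.setdefault("part", mesh.element_part)

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" '
        'format="ascii">',
        "          " + _fmt(mesh.nodes),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "          " + _fmt(mesh.elements),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + _fmt(np.arange(1, n_cells + 1) * npe),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        "          " + _fmt(np.full(n_cells, ctype, dtype=np.uint8)),
        "        </DataArray>",
        "      </Cells>",
    ]

    def data_block(tag: str, data: dict, n_expected: int) -> list[str]:
        out = [f"      <{tag}>"]
        for name, arr in data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            if arr.shape[0] != n_expected:
                raise ValueError(
                    f"array {name!r} has {arr.shape[0]} entries, expected "
                    f"{n_expected}"
                )
            vtype = "Int64" if arr.dtype.kind in "iu" else "Float64"
            out.append(
                f'        <DataArray type="{vtype}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            out.append("          " + _fmt(arr))
            out.append("        </DataArray>")
        out.append(f"      </{tag}>")
        return out

    lines += data_block("CellData", cell_data, n_cells)
    if point_data:
        lines += data_block("PointData", point_data, n_pts)
    lines += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines))
    return path
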