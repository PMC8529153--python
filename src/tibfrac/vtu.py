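"""Minimal ASCII VTU (VTK XML UnstructuredGrid) writer for TET10 meshes.

Writes displacement/stress fields alongside region tags so results open
directly in ParaView.  Only what the pipeline exports is implemented.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_VTK_TET10 = 24


def _data_array(name: str, values: np.ndarray, n_comp: int | None = None) -> str:
    arr = np.asarray(values)
    if arr.ndim == 1:
        n_comp = n_comp or 1
        flat = arr
    else:
        n_comp = arr.shape[1]
        flat = arr.reshape(-1)
    if np.issubdtype(arr.dtype, np.integer):
        vtype, fmt = "Int64", "%d"
    else:
        vtype, fmt = "Float64", "%.12g"
    body = " ".join(fmt % v for v in flat)
    return (f'<DataArray type="{vtype}" Name="{name}" '
            f'NumberOfComponents="{n_comp}" format="ascii">\n{body}\n'
            f"</DataArray>")


def write_vtu(path: str | Path, mesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    nodes = np.asarray(mesh.nodes, dtype=float)
    elements = np.asarray(mesh.elements, dtype=np.int64)
    n_pts, n_cells = len(nodes), len(elements)

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             "<UnstructuredGrid>",
             f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
             "<Points>", _data_array("Points", nodes), "</Points>",
             "<Cells>",
             _data_array("connectivity", elements.reshape(-1)),
             _data_array("offsets", np.arange(1, n_cells + 1) * 10),
             _data_array("types", np.full(n_cells, _VTK_TET10, dtype=np.int64)),
             "</Cells>"]
    if point_data:
        parts.append("<PointData>")
        parts += [_data_array(k, v) for k, v in point_data.items()]
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        parts += [_data_array(k, np.asarray(v)) for k, v in cell_data.items()]
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))
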