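"""Minimal VTK XML (.vtu) writer for leakage-path visualisation.

Writes the shell mesh as an unstructured triangle grid with the nodal
pressure and gap as point data and the element flux (and its magnitude)
as cell data, viewable in ParaView.  ASCII format, no timestamps, so
identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import ShellMesh

__all__ = ["write_vtu"]


def _data_array(name: str, values: np.ndarray, indent: str) -> str:
    values = np.asarray(values, dtype=float)
    ncomp = 1 if values.ndim == 1 else values.shape[1]
    body = " ".join(f"{x:.10g}" for x in values.ravel())
    return (
        f'{indent}<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{ncomp}" format="ascii">{body}</DataArray>\n'
    )


def write_vtu(
    mesh: ShellMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    point_data = point_data or {}
    cell_data = cell_data or {}
    n, m = mesh.n_points, mesh.n_triangles
    parts = [
        '<?xml version="1.0"?>\n',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n',
        "  <UnstructuredGrid>\n",
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n',
        "      <Points>\n",
        _data_array("Points", mesh.points, "        "),
        "      </Points>\n",
        "      <Cells>\n",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">'
        + " ".join(map(str, mesh.triangles.ravel()))
        + "</DataArray>\n",
        '        <DataArray type="Int64" Name="offsets" format="ascii">'
        + " ".join(str(3 * (i + 1)) for i in range(m))
        + "</DataArray>\n",
        '        <DataArray type="UInt8" Name="types" format="ascii">'
        + " ".join(["5"] * m)
        + "</DataArray>\n",
        "      </Cells>\n",
    ]
    if point_data:
        parts.append("      <PointData>\n")
        for name, values in point_data.items():
            parts.append(_data_array(name, values, "        "))
        parts.append("      </PointData>\n")
    if cell_data:
        parts.append("      <CellData>\n")
        for name, values in cell_data.items():
            parts.append(_data_array(name, values, "        "))
        parts.append("      </CellData>\n")
    parts += ["    </Piece>\n", "  </UnstructuredGrid>\n", "</VTKFile>\n"]
    path = Path(path)
    path.write_text("".join(parts))
    return path
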