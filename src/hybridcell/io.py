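"""Export helpers: VTU (unstructured-grid XML), OBJ surfaces, CSV tables.

The VTU writer emits plain ASCII VTK XML — one unstructured grid with
optional point- and cell-data arrays — which ParaView and friends read
directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VTK_TRIANGLE = 5
VTK_TETRA = 10


def write_vtu(path, vertices: np.ndarray, cells: np.ndarray,
              point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write an unstructured grid (triangles or tetrahedra) as ASCII VTU."""
    vertices = np.asarray(vertices, float)
    cells = np.asarray(cells)
    n_pts, n_cells = len(vertices), len(cells)
    ctype = VTK_TRIANGLE if cells.shape[1] == 3 else VTK_TETRA

    def arr(fh, name, data, n_comp=1, kind="Float64"):
        fh.write(f'        <DataArray type="{kind}" Name="{name}" '
                 f'NumberOfComponents="{n_comp}" format="ascii">\n')
        flat = np.asarray(data).reshape(-1)
        fh.write(" ".join(f"{v:.9g}" if kind == "Float64" else str(int(v))
                          for v in flat))
        fh.write("\n        </DataArray>\n")

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n'
                 '<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n'
                 '  <UnstructuredGrid>\n'
                 f'    <Piece NumberOfPoints="{n_pts}" '
                 f'NumberOfCells="{n_cells}">\n')
        fh.write("      <Points>\n")
        arr(fh, "Points", vertices, 3)
        fh.write("      </Points>\n      <Cells>\n")
        arr(fh, "connectivity", cells, 1, "Int64")
        arr(fh, "offsets",
            np.arange(1, n_cells + 1) * cells.shape[1], 1, "Int64")
        arr(fh, "types", np.full(n_cells, ctype), 1, "UInt8")
        fh.write("      </Cells>\n")
        if point_data:
            fh.write("      <PointData>\n")
            for name, data in point_data.items():
                arr(fh, name, data)
            fh.write("      </PointData>\n")
        if cell_data:
            fh.write("      <CellData>\n")
            for name, data in cell_data.items():
                arr(fh, name, data)
            fh.write("      </CellData>\n")
        fh.write("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")


def write_obj(path, vertices: np.ndarray, triangles: np.ndarray) -> None:
    """Plain obj-style surface export."""
    with open(path, "w") as fh:
        for v in np.asarray(vertices, float):
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in np.asarray(triangles):
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def potential_table(t: np.ndarray, V: np.ndarray) -> pd.DataFrame:
    """Long-format (t, compartment_index, V_m) time-series table."""
    n_t, n_c = V.shape
    return pd.DataFrame({
        "t": np.repeat(t, n_c),
        "compartment_index": np.tile(np.arange(n_c), n_t),
        "V_m": V.reshape(-1),
    })


def probe_table(t: np.ndarray, probes: np.ndarray) -> pd.DataFrame:
    """Long-format (t, point_id, c) probe time-series table."""
    n_t, n_p = probes.shape
    return pd.DataFrame({
        "t": np.repeat(t, n_p),
        "point_id": np.tile(np.arange(n_p), n_t),
        "c": probes.reshape(-1),
    })


def mapping_table(surface_vertices: np.ndarray,
                  nn_index: np.ndarray) -> pd.DataFrame:
    """Surface-vertex -> compartment-node mapping table."""
    return pd.DataFrame({
        "vertex": np.arange(len(surface_vertices)),
        "x": surface_vertices[:, 0],
        "y": surface_vertices[:, 1],
        "z": surface_vertices[:, 2],
        "compartment_node": nn_index,
    })
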