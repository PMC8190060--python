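"""Plain-text writers for meshes and fields (VTU XML and Gmsh MSH 4.1)."""

from __future__ import annotations

import numpy as np

from .meshing import Mesh

__all__ = ["write_vtu", "write_msh41", "flow_point_data"]


def flow_point_data(flow) -> dict:
    """Vertex-sampled velocity/pressure/shear arrays for field export."""
    pts = flow.mesh.points
    vel = flow.u[:len(pts)]
    tau = flow.fluid.dynamic_viscosity * np.nan_to_num(flow.shear_rate(pts))
    return {"velocity_m_s": vel, "pressure_pa": flow.p, "shear_pa": tau}


def _ascii(arr) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(arr).ravel())


def write_vtu(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Serial VTK unstructured-grid XML (ASCII) with triangle cells."""
    pts3 = np.column_stack([mesh.points, np.zeros(len(mesh.points))])
    n_p, n_c = mesh.n_points, mesh.n_triangles
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_p}" NumberOfCells="{n_c}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _ascii(pts3), "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        " ".join(map(str, mesh.triangles.ravel())), "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(map(str, range(3, 3 * n_c + 1, 3))), "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(["5"] * n_c), "</DataArray>", "</Cells>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            if ncomp == 2:  # pad vectors to 3D for VTK
                arr = np.column_stack([arr, np.zeros(len(arr))])
                ncomp = 3
            lines += [f'<DataArray type="Float64" Name="{name}" '
                      f'NumberOfComponents="{ncomp}" format="ascii">',
                      _ascii(arr), "</DataArray>"]
        lines.append("</PointData>")
    if cell_data:
        lines.append("<CellData>")
        for name, arr in cell_data.items():
            lines += [f'<DataArray type="Float64" Name="{name}" format="ascii">',
                      _ascii(arr), "</DataArray>"]
        lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_msh41(mesh: Mesh, path) -> None:
    """Minimal Gmsh MSH 4.1 ASCII file: one surface entity, triangle elements."""
    n_p = mesh.n_points
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        fh.write("$Entities\n0 0 1 0\n1 ")
        x0, y0 = mesh.points.min(axis=0)
        x1, y1 = mesh.points.max(axis=0)
        fh.write(f"{x0} {y0} 0 {x1} {y1} 0 0 0\n$EndEntities\n")
        fh.write(f"$Nodes\n1 {n_p} 1 {n_p}\n2 1 0 {n_p}\n")
        for i in range(n_p):
            fh.write(f"{i + 1}\n")
        for x, y in mesh.points:
            fh.write(f"{x} {y} 0\n")
        fh.write("$EndNodes\n")
        n_c = mesh.n_triangles
        fh.write(f"$Elements\n1 {n_c} 1 {n_c}\n2 1 2 {n_c}\n")
        for i, tri in enumerate(mesh.triangles):
            fh.write(f"{i + 1} {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
        fh.write("$EndElements\n")
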