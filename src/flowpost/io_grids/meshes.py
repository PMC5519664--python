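"""Triangle-mesh I/O: binary STL, ASCII PLY, and VTK XML PolyData (VTP).

Minimal codecs for the three formats the pipeline emits; vertex units are
millimetres throughout.  The VTP writer can attach per-face scalar data
(e.g. wall shear stress magnitude) so meshes open directly in ParaView.
"""

from __future__ import annotations

import struct
import xml.etree.ElementTree as ET
from typing import Optional

import numpy as np

from .types import TriMesh

__all__ = ["write_mesh", "read_mesh", "MESH_FORMATS"]

MESH_FORMATS = ("stl", "ply", "vtp")


def _detect(path: str, fmt: Optional[str]) -> str:
    name = (fmt or path.rsplit(".", 1)[-1]).lower()
    if name not in MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {name!r}; expected one of {MESH_FORMATS}")
    return name


# -- STL (binary) -----------------------------------------------------------

def _write_stl(mesh: TriMesh, path: str) -> None:
    tri = mesh.vertices[mesh.faces].astype("<f4")
    normals = mesh.face_normals.astype("<f4")
    with open(path, "wb") as fh:
        fh.write(b"flowpost binary STL".ljust(80, b" "))
        fh.write(struct.pack("<I", mesh.n_faces))
        record = np.zeros(mesh.n_faces, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                                               ("attr", "<u2")])
        record["n"] = normals
        record["v"] = tri
        fh.write(record.tobytes())


def _read_stl(path: str) -> TriMesh:
    with open(path, "rb") as fh:
        fh.read(80)
        (n_faces,) = struct.unpack("<I", fh.read(4))
        record = np.frombuffer(fh.read(n_faces * 50),
                               dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
    tri = record["v"].astype(float).reshape(-1, 3)
    # STL stores vertices per facet; merge exact duplicates to recover topology
    vertices, inverse = np.unique(tri, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriMesh(vertices=vertices, faces=faces)


# -- PLY (ascii) ------------------------------------------------------------

def _write_ply(mesh: TriMesh, path: str) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        "comment flowpost surface, vertex units mm",
        f"element vertex {len(mesh.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines.extend(" ".join(repr(float(c)) for c in v) for v in mesh.vertices)
    lines.extend("3 " + " ".join(str(int(i)) for i in f) for f in mesh.faces)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_ply(path: str) -> TriMesh:
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vertices = n_faces = 0
        for line in fh:
            token = line.split()
            if token[:2] == ["element", "vertex"]:
                n_vertices = int(token[2])
            elif token[:2] == ["element", "face"]:
                n_faces = int(token[2])
            elif token[0] == "end_header":
                break
        vertices = np.array([fh.readline().split() for _ in range(n_vertices)], dtype=float)
        faces = np.array([fh.readline().split()[1:4] for _ in range(n_faces)], dtype=np.int64)
    return TriMesh(vertices=vertices[:, :3], faces=faces)


# -- VTP (VTK XML PolyData, ascii) ------------------------------------------

def _write_vtp(mesh: TriMesh, path: str,
               cell_data: Optional[dict[str, np.ndarray]] = None) -> None:
    root = ET.Element("VTKFile", type="PolyData", version="0.1", byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(poly, "Piece",
                          NumberOfPoints=str(len(mesh.vertices)),
                          NumberOfPolys=str(mesh.n_faces))
    points = ET.SubElement(piece, "Points")
    arr = ET.SubElement(points, "DataArray", type="Float64",
                        NumberOfComponents="3", format="ascii")
    arr.text = " ".join(repr(float(c)) for c in mesh.vertices.ravel())
    polys = ET.SubElement(piece, "Polys")
    conn = ET.SubElement(polys, "DataArray", type="Int64", Name="connectivity", format="ascii")
    conn.text = " ".join(str(int(i)) for i in mesh.faces.ravel())
    offs = ET.SubElement(polys, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = " ".join(str(3 * (i + 1)) for i in range(mesh.n_faces))
    if cell_data:
        cd = ET.SubElement(piece, "CellData")
        for name, values in cell_data.items():
            values = np.asarray(values, dtype=float)
            da = ET.SubElement(cd, "DataArray", type="Float64", Name=name,
                               NumberOfComponents=str(1 if values.ndim == 1 else values.shape[1]),
                               format="ascii")
            da.text = " ".join(repr(float(v)) for v in values.ravel())
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _read_vtp(path: str) -> TriMesh:
    root = ET.parse(path).getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTP PolyData file")
    pts = piece.find("./Points/DataArray")
    vertices = np.array(pts.text.split(), dtype=float).reshape(-1, 3)
    conn = piece.find("./Polys/DataArray[@Name='connectivity']")
    faces = np.array(conn.text.split(), dtype=np.int64).reshape(-1, 3)
    return TriMesh(vertices=vertices, faces=faces)


# -- public API -------------------------------------------------------------

def write_mesh(mesh: TriMesh, path: str, fmt: Optional[str] = None,
               cell_data: Optional[dict[str, np.ndarray]] = None) -> None:
    """Write a mesh; ``cell_data`` (per-face arrays) is supported for VTP."""
    name = _detect(path, fmt)
    if name == "stl":
        _write_stl(mesh, path)
    elif name == "ply":
        _write_ply(mesh, path)
    else:
        _write_vtp(mesh, path, cell_data=cell_data)


def read_mesh(path: str, fmt: Optional[str] = None) -> TriMesh:
    name = _detect(path, fmt)
    if name == "stl":
        return _read_stl(path)
    if name == "ply":
        return _read_ply(path)
    return _read_vtp(path)
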