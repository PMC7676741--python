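"""Triangulated bladder-surface meshes: STL I/O, validation, volume and centroid.

Coordinates are interpreted as millimetres throughout. STL carries no unit
metadata, so this is a package-wide convention (segmentation tools such as
Mimics export in the image's native mm frame); the CLI exposes a scale
override for exports in other units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "ValidationReport",
    "read_stl",
    "write_stl",
    "validate_mesh",
    "mesh_volume",
    "mesh_centroid",
]

#: Vertex welding tolerance on STL read (mm). STL stores each facet's corners
#: independently; downstream edge-topology checks need shared vertices.
WELD_TOL = 1e-6

#: Faces with area below this (mm^2) are considered degenerate.
DEGENERATE_AREA = 1e-12


@dataclass
class SurfaceMesh:
    """A triangulated closed surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices, counter-clockwise when viewed
        from outside (outward normals) after validation/repair.
    provenance : free-text label, e.g. ``"pre-void"`` or ``"synthetic"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.provenance)

    def translated(self, offset) -> "SurfaceMesh":
        return replace(self, vertices=self.vertices + np.asarray(offset, float))

    def scaled(self, s: float) -> "SurfaceMesh":
        return replace(self, vertices=self.vertices * float(s))

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class ValidationReport:
    """Topology/geometry report; a mesh passing all three checks is safe for
    volume integration and ray casting."""

    closed: bool
    oriented: bool
    degenerate_faces: int
    boundary_edges: int = 0
    duplicate_directed_edges: int = 0

    @property
    def ok(self) -> bool:
        return self.closed and self.oriented and self.degenerate_faces == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "closed": self.closed,
                "oriented": self.oriented,
                "degenerate_faces": self.degenerate_faces,
                "boundary_edges": self.boundary_edges,
                "duplicate_directed_edges": self.duplicate_directed_edges,
                "ok": self.ok,
            }
        )


def _face_areas(mesh: SurfaceMesh) -> np.ndarray:
    tri = mesh.triangles()
    return 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )


def validate_mesh(mesh: SurfaceMesh) -> ValidationReport:
    """Check closedness (every edge shared by exactly two faces), consistent
    outward orientation, and degenerate faces. Reports, never raises."""
    faces = mesh.faces
    degenerate = int(
        np.sum(
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        )
    )
    if len(faces):
        degenerate = max(degenerate, int(np.sum(_face_areas(mesh) < DEGENERATE_AREA)))

    # directed edges; consistent orientation => each undirected edge appears
    # once per direction
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    directed = e[:, 0] * (mesh.n_vertices + 1) + e[:, 1]
    undirected_a = np.minimum(e[:, 0], e[:, 1])
    undirected_b = np.maximum(e[:, 0], e[:, 1])
    undirected = undirected_a * (mesh.n_vertices + 1) + undirected_b

    _, dir_counts = np.unique(directed, return_counts=True)
    _, und_counts = np.unique(undirected, return_counts=True)

    boundary = int(np.sum(und_counts != 2))
    dup_directed = int(np.sum(dir_counts > 1))
    closed = boundary == 0 and len(faces) > 0
    oriented = closed and dup_directed == 0
    return ValidationReport(
        closed=closed,
        oriented=oriented,
        degenerate_faces=degenerate,
        boundary_edges=boundary,
        duplicate_directed_edges=dup_directed,
    )


def _signed_volume(mesh: SurfaceMesh) -> float:
    # sum of signed tetrahedra against the coordinate origin; exact for
    # closed surfaces, independent of the origin choice
    tri = mesh.triangles()
    return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (mm^3) of a closed mesh via the divergence theorem."""
    report = validate_mesh(mesh)
    if not report.closed:
        raise ValueError(
            f"mesh is not closed ({report.boundary_edges} boundary edge(s)); "
            "volume is undefined"
        )
    return abs(_signed_volume(mesh))


def mesh_centroid(mesh: SurfaceMesh) -> np.ndarray:
    """Volume-weighted centroid (mm) of the enclosed solid (not the vertex
    mean, which would be biased by non-uniform surface sampling)."""
    report = validate_mesh(mesh)
    if not report.closed:
        raise ValueError(
            f"mesh is not closed ({report.boundary_edges} boundary edge(s)); "
            "centroid is undefined"
        )
    tri = mesh.triangles()
    w = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    total = w.sum()
    if abs(total) < 1e-12:
        raise ValueError("mesh encloses (numerically) zero volume")
    # tetrahedron {0, v0, v1, v2} centroid is (v0+v1+v2)/4
    c = (tri.sum(axis=1) / 4.0 * w[:, None]).sum(axis=0) / total
    return c


def orient_outward(mesh: SurfaceMesh) -> SurfaceMesh:
    """Flip all faces if the signed volume is negative (inward winding).
    Segmentation exports vary in winding convention; flipping is cheaper and
    safer than refusing them."""
    if len(mesh.faces) and _signed_volume(mesh) < 0:
        return replace(mesh, faces=mesh.faces[:, ::-1].copy())
    return mesh


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float):
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def read_stl(path, weld_tol: float = WELD_TOL) -> SurfaceMesh:
    """Read a binary or ASCII STL file.

    Duplicate vertices within ``weld_tol`` mm are welded so edge topology is
    well defined; winding is repaired to outward if the mesh is closed.
    """
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise ValueError(f"could not read STL file {path!r}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"STL file {path!r} contains no facets")
    vertices, faces = _weld(
        np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64), weld_tol
    )
    mesh = SurfaceMesh(vertices, faces, provenance=str(path))
    if validate_mesh(mesh).closed:
        mesh = orient_outward(mesh)
    return mesh


def write_stl(mesh: SurfaceMesh, path) -> None:
    """Write a binary STL. The mesh must validate (closed, oriented, no
    degenerate faces); writing a broken mesh would poison downstream runs."""
    report = validate_mesh(mesh)
    if not report.ok:
        raise ValueError(f"refusing to write invalid mesh: {report.to_json()}")
    mesh.to_trimesh().export(str(path), file_type="stl")
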