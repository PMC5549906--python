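"""Triangle-mesh container and vertex welding.

A scan from an intra-oral scanner arrives as an STL or PLY triangle mesh.
STL stores each triangle's three corners independently, so a mesh of a
75 mm wafer typically carries six records per interior vertex; welding
merges positions that coincide (within a tolerance far below scanner
resolution) back into shared vertices, which every downstream operation
assumes. Coordinates are interpreted as millimetres throughout the
package; vertex-to-plane distances are reported in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import EmptyMeshError, ParameterError

#: Default weld tolerance in millimetres. Far below the ~35 um resolution
#: of the scanners this package targets, but large enough to absorb
#: float32 round-off in STL files.
DEFAULT_WELD_TOL_MM = 1e-6


@dataclass
class TriangleMesh:
    """A triangle mesh with vertex coordinates in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    faces : (m, 3) int array
        Indices into ``vertices``; each row is one triangle.
    name : str
        Optional provenance tag (filename, simulation condition, ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- basic properties -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def bbox_diagonal(self) -> float:
        """Length of the axis-aligned bounding-box diagonal (mm)."""
        if self.n_vertices == 0:
            return 0.0
        extent = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(extent))

    # -- validation -------------------------------------------------------
    def validate(self) -> "TriangleMesh":
        """Check structural invariants; return self for chaining.

        Raises
        ------
        EmptyMeshError
            If there are no vertices or no faces.
        ParameterError
            If coordinates are non-finite, a face index is out of range,
            or a face repeats a vertex index.
        """
        if self.n_vertices == 0 or self.n_faces == 0:
            raise EmptyMeshError(
                f"mesh {self.name!r} is empty "
                f"({self.n_vertices} vertices, {self.n_faces} faces)"
            )
        if not np.isfinite(self.vertices).all():
            raise ParameterError(f"mesh {self.name!r} has non-finite coordinates")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            raise ParameterError(f"mesh {self.name!r} has out-of-range face indices")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ParameterError(f"mesh {self.name!r} has degenerate faces")
        return self

    # -- welding ----------------------------------------------------------
    def weld(self, tolerance_mm: float = DEFAULT_WELD_TOL_MM) -> "TriangleMesh":
        """Merge vertices closer than ``tolerance_mm`` into one.

        Clusters of mutually close vertices (found by a KD-tree pair query
        and union-find) are collapsed onto the lowest-index member, faces
        are re-indexed and faces made degenerate by the merge are dropped.
        Welding an already-welded mesh is a no-op.
        """
        if tolerance_mm < 0:
            raise ParameterError("weld tolerance must be non-negative")
        if self.n_vertices == 0:
            return replace(self)
        tree = cKDTree(self.vertices)
        pairs = tree.query_pairs(tolerance_mm, output_type="ndarray")
        parent = np.arange(self.n_vertices)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in pairs:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                # keep the lower index as representative
                lo, hi = (ra, rb) if ra < rb else (rb, ra)
                parent[hi] = lo

        roots = np.fromiter((find(i) for i in range(self.n_vertices)), dtype=np.int64)
        kept, inverse = np.unique(roots, return_inverse=True)
        new_vertices = self.vertices[kept]
        new_faces = inverse[self.faces]
        ok = (
            (new_faces[:, 0] != new_faces[:, 1])
            & (new_faces[:, 1] != new_faces[:, 2])
            & (new_faces[:, 0] != new_faces[:, 2])
        )
        return TriangleMesh(new_vertices, new_faces[ok], name=self.name)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TriangleMesh":
        """Apply a rigid motion ``v -> R v + t`` and return the new mesh."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriangleMesh(v, self.faces.copy(), name=self.name)


def submesh(mesh: TriangleMesh, keep: np.ndarray, name: str | None = None) -> TriangleMesh:
    """Restrict ``mesh`` to the vertices flagged in boolean mask ``keep``.

    Faces touching a removed vertex are dropped and the surviving vertex
    indices are compacted. Kept vertices that end up unreferenced by any
    face are retained (the roughness field is vertex-based).
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.shape[0] != mesh.n_vertices:
        raise ParameterError("keep mask length does not match vertex count")
    new_index = np.full(mesh.n_vertices, -1, dtype=np.int64)
    new_index[keep] = np.arange(int(keep.sum()))
    face_ok = keep[mesh.faces].all(axis=1)
    return TriangleMesh(
        mesh.vertices[keep],
        new_index[mesh.faces[face_ok]],
        name=mesh.name if name is None else name,
    )
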