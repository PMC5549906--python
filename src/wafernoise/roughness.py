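"""Roughness field, Rq statistic, distance bins, cropping and ROI.

The noise of a scanner imaging an ultra-flat wafer is quantified as
surface roughness: for every vertex, a mean plane is fitted (total least
squares) to all vertices inside a ball of a chosen kernel radius, and the
signed orthogonal distance of the vertex to that plane is recorded in
micrometres. Rq is the root mean square of those distances. With a kernel
radius that covers the whole mesh, the method reduces to residuals from a
single global plane fit -- a virtual flat reference surface.

Cropping and the central region of interest (ROI) operate in the frame of
the globally fitted plane, not world coordinates, so that tilted scans
(30 deg / 45 deg acquisitions) are cropped to the same physical region as
untilted ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import (
    DegenerateGeometryError,
    EmptyInputError,
    EmptyResultError,
    ParameterError,
)
from .mesh import TriangleMesh, submesh

#: Default kernel radius (mm): large enough that the entire cropped wafer
#: mesh falls in a single neighborhood, making the local fit a global one.
DEFAULT_KERNEL_RADIUS_MM = 20.0

#: Default distance-bin edges in micrometres.
DEFAULT_BIN_EDGES_UM = (5.0, 10.0, 20.0)

#: Signed distances smaller than this (um) are snapped to exactly zero.
#: It is ~7 orders of magnitude below scanner noise and exists only so
#: that a perfectly planar mesh yields a roughness field of exact zeros
#: instead of float round-off residue.
SNAP_TOL_UM = 1e-7


@dataclass(frozen=True)
class Plane:
    """The plane {p : normal . p = offset}, with a unit normal.

    ``normal`` is dimensionless; ``offset`` carries the coordinate unit
    (mm). The sign of ``normal`` is canonicalized so that its largest-
    magnitude component is positive, making fits reproducible.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float).ravel()
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            n = n / norm
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed orthogonal distance of points to the plane (same unit)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.normal - self.offset

    def flipped(self) -> "Plane":
        p = Plane.__new__(Plane)
        object.__setattr__(p, "normal", -self.normal)
        object.__setattr__(p, "offset", -self.offset)
        return p


@dataclass
class RoughnessField:
    """Per-vertex signed distance (um) to the locally fitted plane."""

    values_um: np.ndarray
    kernel_radius_mm: float
    mesh: TriangleMesh

    def __post_init__(self) -> None:
        self.values_um = np.asarray(self.values_um, dtype=float).ravel()
        if self.values_um.shape[0] != self.mesh.n_vertices:
            raise ParameterError("field length does not match mesh vertex count")
        if not np.isfinite(self.values_um).all():
            raise ParameterError("roughness field contains non-finite values")

    def __len__(self) -> int:
        return int(self.values_um.shape[0])

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular export: vertex index, coordinates (mm), distance (um)."""
        v = self.mesh.vertices
        return pd.DataFrame(
            {
                "vertex": np.arange(len(self)),
                "x_mm": v[:, 0],
                "y_mm": v[:, 1],
                "z_mm": v[:, 2],
                "distance_um": self.values_um,
            }
        )


@dataclass(frozen=True)
class BinCounts:
    """Proportions of vertices in half-open |distance| bins.

    With the default edges (5, 10, 20 um) the bins are [0,5), [5,10),
    [10,20) and [20, inf) micrometres; lower edges are inclusive.
    """

    proportions: np.ndarray
    edges_um: tuple = DEFAULT_BIN_EDGES_UM

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float).ravel()
        object.__setattr__(self, "proportions", p)
        if p.shape[0] != len(self.edges_um) + 1:
            raise ParameterError("need one proportion per bin")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ParameterError("bin proportions must be non-negative and sum to 1")


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane through >=3 non-collinear points.

    The plane passes through the centroid and its normal is the direction
    of least variance of the centered points (smallest right singular
    vector), which minimizes the sum of squared orthogonal distances.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"plane fit needs at least 3 points, got {pts.shape[0]}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the n x 3 centered cloud; singular values sorted descending
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= max(s[0], np.finfo(float).tiny) * 1e-12:
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    normal = vt[2]
    # canonical sign: largest-|component| positive
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    return Plane(normal=normal, offset=float(normal @ centroid))


def plane_basis(plane: Plane) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane axes (u, v) for a plane.

    u is built from the world axis least aligned with the normal, so for
    a horizontal plane the in-plane frame coincides with the world x/y
    axes (up to sign/order).
    """
    n = plane.normal
    e = np.zeros(3)
    e[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(n, e)
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _inplane_coords(mesh: TriangleMesh) -> np.ndarray:
    """Project vertices onto the global fitted plane's in-plane axes."""
    plane = fit_plane(mesh.vertices)
    u, v = plane_basis(plane)
    return mesh.vertices @ np.stack([u, v], axis=1)


def _rect_mask(uv: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    eps = 1e-9 * max(float((hi - lo).max()), 1.0)
    return ((uv >= lo - eps) & (uv <= hi + eps)).all(axis=1)


def crop_border(mesh: TriangleMesh, margin_fraction: float = 0.05) -> TriangleMesh:
    """Remove a border band: shrink the in-plane bounding rectangle.

    ``margin_fraction`` of the in-plane bounding box is cut from *each*
    side; 0 keeps the mesh unchanged. Used to eliminate the wafer edges
    before computing roughness.
    """
    if not 0 <= margin_fraction < 0.5:
        raise ParameterError(
            f"margin_fraction must be in [0, 0.5), got {margin_fraction}"
        )
    mesh.validate()
    if margin_fraction == 0:
        return mesh
    uv = _inplane_coords(mesh)
    lo, hi = uv.min(axis=0), uv.max(axis=0)
    span = hi - lo
    keep = _rect_mask(uv, lo + margin_fraction * span, hi - margin_fraction * span)
    if not keep.any():
        raise EmptyResultError("cropping removed every vertex")
    return submesh(mesh, keep)


def central_roi(mesh: TriangleMesh, roi_fraction: float = 0.5) -> TriangleMesh:
    """Select the centered in-plane rectangle covering ``roi_fraction``
    of each bounding-box axis -- the central region used to separate
    border behaviour (edge effect) from the middle of the scan."""
    if not 0 < roi_fraction <= 1:
        raise ParameterError(f"roi_fraction must be in (0, 1], got {roi_fraction}")
    mesh.validate()
    uv = _inplane_coords(mesh)
    lo, hi = uv.min(axis=0), uv.max(axis=0)
    center, half = (lo + hi) / 2, (hi - lo) / 2 * roi_fraction
    keep = _rect_mask(uv, center - half, center + half)
    if not keep.any():
        raise EmptyResultError("ROI selection removed every vertex")
    return submesh(mesh, keep)


def roughness_field(mesh: TriangleMesh,
                    kernel_radius_mm: float = DEFAULT_KERNEL_RADIUS_MM,
                    snap_tol_um: float = SNAP_TOL_UM) -> RoughnessField:
    """Signed vertex-to-local-plane distances (um) with a ball kernel.

    For each vertex, all vertices within ``kernel_radius_mm`` (itself
    included) define the neighborhood; a total-least-squares plane is
    fitted to them and the vertex's signed orthogonal distance recorded.
    Local normals are oriented consistently with the global fitted plane,
    so 'above' and 'below' mean the same thing across the mesh.

    When the radius covers the whole mesh every neighborhood is the full
    vertex set, and the computation collapses to residuals from the single
    global plane (a fast path; bit-identical to the general one).
    """
    if kernel_radius_mm <= 0:
        raise ParameterError(f"kernel radius must be positive, got {kernel_radius_mm}")
    mesh.validate()
    V = mesh.vertices
    global_plane = fit_plane(V)
    if kernel_radius_mm >= mesh.bbox_diagonal():
        dist_mm = global_plane.signed_distance(V)
    else:
        tree = cKDTree(V)
        neighborhoods = tree.query_ball_point(V, kernel_radius_mm)
        dist_mm = np.empty(mesh.n_vertices)
        for i, idx in enumerate(neighborhoods):
            if len(idx) < 3:
                raise DegenerateGeometryError(
                    f"vertex {i}: only {len(idx)} neighbors within "
                    f"{kernel_radius_mm} mm; cannot fit a plane"
                )
            try:
                local = fit_plane(V[idx])
            except DegenerateGeometryError as exc:
                raise DegenerateGeometryError(f"vertex {i}: {exc}") from exc
            if local.normal @ global_plane.normal < 0:
                local = local.flipped()
            dist_mm[i] = local.normal @ V[i] - local.offset
    values_um = dist_mm * 1000.0
    values_um[np.abs(values_um) < snap_tol_um] = 0.0
    return RoughnessField(values_um, kernel_radius_mm, mesh)


def rms(values) -> float:
    """Rq = sqrt(mean of squared distances), in micrometres.

    Accepts a RoughnessField or any sequence of distances; the sign of the
    distances is irrelevant. Population form (divide by n).
    """
    if isinstance(values, RoughnessField):
        x = values.values_um
    else:
        x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("Rq of an empty set of distances is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def bin_proportions(values, edges_um: tuple = DEFAULT_BIN_EDGES_UM) -> BinCounts:
    """Proportions of |distance| in half-open bins [0,e1), [e1,e2), ...

    Lower edges are inclusive: a distance of exactly 5 um falls in the
    5-10 um bin.
    """
    if isinstance(values, RoughnessField):
        x = values.values_um
    else:
        x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("bin proportions of an empty field are undefined")
    edges = tuple(float(e) for e in edges_um)
    if any(e <= 0 for e in edges) or list(edges) != sorted(set(edges)):
        raise ParameterError("bin edges must be positive and strictly increasing")
    counts, _ = np.histogram(np.abs(x), bins=[0.0, *edges, np.inf])
    return BinCounts(counts / x.size, edges_um=edges)
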