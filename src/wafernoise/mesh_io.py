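"""Reading and writing triangle meshes (STL, PLY) and colored distance maps.

STL auto-detection follows common practice for malformed files: a file is
treated as ASCII if it starts with ``solid`` *and* parses as ASCII STL;
otherwise it must satisfy the binary layout (80-byte header, uint32
triangle count, 50-byte records) exactly. Parsing itself is delegated to
trimesh; this module adds the detection/consistency checks, welding on
import, and a per-vertex-colored ASCII PLY writer used for the false-color
distance maps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import EmptyMeshError, MeshFormatError, ParameterError
from .mesh import DEFAULT_WELD_TOL_MM, TriangleMesh

_STL_HEADER_BYTES = 84  # 80-byte comment + uint32 triangle count
_STL_RECORD_BYTES = 50


def _detect_stl_kind(raw: bytes, path: Path) -> str:
    """Classify STL bytes as 'ascii' or 'binary', or raise MeshFormatError."""
    stripped = raw.lstrip()
    looks_ascii = stripped.startswith(b"solid")
    if looks_ascii and b"facet" in raw:
        return "ascii"
    # binary layout check
    if len(raw) < _STL_HEADER_BYTES:
        raise MeshFormatError(
            f"{path}: {len(raw)} bytes is too short for binary STL "
            f"(needs at least {_STL_HEADER_BYTES}) and no ASCII 'facet' found"
        )
    n_tri = int(np.frombuffer(raw[80:84], dtype="<u4")[0])
    expected = _STL_HEADER_BYTES + n_tri * _STL_RECORD_BYTES
    if len(raw) != expected:
        raise MeshFormatError(
            f"{path}: binary STL declares {n_tri} triangles at byte offset 80, "
            f"expected {expected} bytes but file has {len(raw)}"
        )
    return "binary"


def read_mesh(path: str | Path, format_hint: str | None = None,
              weld_tolerance_mm: float = DEFAULT_WELD_TOL_MM) -> TriangleMesh:
    """Read an STL (ASCII or binary) or PLY mesh and weld duplicate vertices.

    Parameters
    ----------
    path : path to the mesh file
    format_hint : 'stl' or 'ply'; inferred from the suffix when omitted
    weld_tolerance_mm : positions closer than this are merged

    Returns
    -------
    TriangleMesh with coordinates interpreted as millimetres.
    """
    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise ParameterError(f"unsupported mesh format {fmt!r} (expected stl or ply)")
    if not path.exists():
        raise MeshFormatError(f"{path}: no such file")
    raw = path.read_bytes()
    try:
        if fmt == "stl":
            _detect_stl_kind(raw, path)  # raises on inconsistent files
        tm = trimesh.load(io.BytesIO(raw), file_type=fmt, force="mesh", process=False)
    except MeshFormatError:
        raise
    except Exception as exc:  # trimesh raises a mix of ValueError/IndexError
        raise MeshFormatError(f"{path}: could not parse as {fmt}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if vertices.size == 0 or faces.size == 0:
        raise EmptyMeshError(f"{path}: mesh has no triangles")
    mesh = TriangleMesh(vertices, faces, name=path.stem).weld(weld_tolerance_mm)
    return mesh.validate()


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str = "stl") -> Path:
    """Write ``mesh`` to ``path`` as binary STL, ASCII STL or ASCII PLY.

    ``format`` is one of 'stl' (binary, 84 + 50*n_faces bytes),
    'stl_ascii', or 'ply'.
    """
    path = Path(path)
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write an empty mesh")
    fmt = format.lower()
    if fmt not in ("stl", "stl_ascii", "ply"):
        raise ParameterError(f"unsupported output format {format!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
        if isinstance(data, str):
            data = data.encode()
    else:
        data = tm.export(file_type=fmt)
        if isinstance(data, str):
            data = data.encode()
    path.write_bytes(data)
    return path


@dataclass(frozen=True)
class LookupTable:
    """Piecewise-linear color scale mapping signed distances (um) to RGB.

    Values are clamped to ``[vmin, vmax]`` before interpolation across the
    equally spaced color ``stops``. The default scale runs blue (below
    plane) through green (on plane) to red (above plane) over +/-20 um,
    matching the distance range used for the vertex classification bins.
    """

    vmin: float = -20.0
    vmax: float = 20.0
    stops: tuple = (
        (0, 0, 255),       # far below the plane
        (0, 255, 255),
        (0, 255, 0),       # on the plane
        (255, 255, 0),
        (255, 0, 0),       # far above
    )

    def __post_init__(self) -> None:
        if not self.vmax > self.vmin:
            raise ParameterError("LUT range must have vmax > vmin")
        if len(self.stops) < 2:
            raise ParameterError("LUT needs at least two color stops")

    def map(self, values: np.ndarray) -> np.ndarray:
        """Map scalars to uint8 RGB, shape (n, 3)."""
        v = np.clip(np.asarray(values, dtype=float), self.vmin, self.vmax)
        t = (v - self.vmin) / (self.vmax - self.vmin)
        xs = np.linspace(0.0, 1.0, len(self.stops))
        stops = np.asarray(self.stops, dtype=float)
        rgb = np.stack([np.interp(t, xs, stops[:, c]) for c in range(3)], axis=1)
        return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def write_colored_mesh(mesh: TriangleMesh, scalars_um: np.ndarray,
                       path: str | Path, lut: LookupTable | None = None) -> Path:
    """Write an ASCII PLY with per-vertex RGB from a scalar field.

    ``scalars_um`` is the signed vertex-to-plane distance in micrometres;
    one value per vertex. Colors come from ``lut`` (default +/-20 um
    blue-green-red scale).
    """
    path = Path(path)
    scalars = np.asarray(scalars_um, dtype=float).ravel()
    if scalars.shape[0] != mesh.n_vertices:
        raise ParameterError(
            f"scalar field has {scalars.shape[0]} values for "
            f"{mesh.n_vertices} vertices"
        )
    if mesh.n_vertices == 0:
        raise EmptyMeshError("refusing to write an empty mesh")
    lut = lut or LookupTable()
    rgb = lut.map(scalars)
    lines = [
        "ply",
        "format ascii 1.0",
        "comment signed vertex-to-plane distance map (micrometres via LUT)",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for (x, y, z), (r, g, b) in zip(mesh.vertices, rgb):
        lines.append(f"{x:.6f} {y:.6f} {z:.6f} {r} {g} {b}")
    for a, b, c in mesh.faces:
        lines.append(f"3 {a} {b} {c}")
    path.write_text("\n".join(lines) + "\n")
    return path
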