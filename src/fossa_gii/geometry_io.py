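"""Mesh and table I/O plus fossa-ovalis / left-atrium geometry derivations.

Everything is millimetres in a right-handed frame, as exported by clinical
CAD.  No global anatomical axes are assumed: the fossa-ovalis (FO) patch
carries its own {superior, posterior} in-plane frame, supplied by the caller
or constructed arbitrarily when only geometry-neutral quantities are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import FormatError, ResolutionError, ValidationError

__all__ = [
    "TriMesh",
    "FOPatch",
    "LASamples",
    "read_mesh",
    "write_mesh",
    "extract_fo_candidates",
    "assign_quadrant",
    "sample_la_interior",
    "read_thickness_csv",
    "write_thickness_csv",
    "write_ply_scalar",
]

QUADRANTS = ("SP", "IP", "SA", "IA")


@dataclass
class TriMesh:
    """Triangulated surface in mm.

    Carrier for left-atrium (LA), right-atrium and FO geometry.  Thin wrapper
    over arrays so that downstream code never depends on a particular mesh
    library; :meth:`as_trimesh` bridges to :mod:`trimesh` where needed.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if not np.isfinite(self.vertices).all():
            raise ValidationError("vertex coordinates must be finite")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array of vertex indices")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValidationError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriMesh":
        """Rigidly transformed copy (vertices -> R v + t)."""
        return TriMesh(self.vertices @ np.asarray(rotation).T + translation, self.faces, self.name)


@dataclass
class FOPatch:
    """FO candidate puncture sites with orientation and thickness.

    ``normals`` are unit vectors pointing from the right into the left atrium
    (the catheter insertion direction).  Following the study convention the
    ``centroid`` is the thinnest point of the FO, not the geometric mean.
    """

    points: np.ndarray
    normals: np.ndarray
    thickness: np.ndarray
    centroid: np.ndarray
    centroid_index: int
    quadrant: np.ndarray = field(default=None)  # type: ignore[assignment]
    superior: np.ndarray | None = None
    posterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("FO normals must be unit vectors (tol 1e-9)")
        if np.any(self.thickness <= 0):
            raise ValidationError("FO thickness must be strictly positive")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class LASamples:
    """Discrete points strictly inside the LA cavity on a regular grid."""

    points: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.spacing <= 0:
            raise ValidationError("spacing must be positive")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def read_mesh(path: str | Path, units: str = "mm") -> TriMesh:
    """Read a binary or ASCII STL file into a :class:`TriMesh` in mm.

    ``units="m"`` scales coordinates by 1000; the default is mm because
    clinical CAD exports use mm.
    """
    path = Path(path)
    if units not in ("mm", "m"):
        raise ValidationError(f"units must be 'mm' or 'm', got {units!r}")
    if not path.exists():
        raise ResolutionError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load_mesh(str(path), file_type=path.suffix.lstrip(".") or "stl")
    except Exception as exc:  # trimesh raises assorted types on corrupt input
        raise FormatError(f"could not parse mesh file {path}: {exc}") from exc
    if mesh.vertices is None or len(mesh.vertices) == 0:
        raise ValidationError(f"mesh file {path} contains no vertices")
    scale = 1000.0 if units == "m" else 1.0
    return TriMesh(np.asarray(mesh.vertices) * scale, np.asarray(mesh.faces), name=path.stem)


def write_mesh(mesh: TriMesh, path: str | Path) -> None:
    """Write a mesh as STL (format chosen by extension, default binary STL)."""
    mesh.as_trimesh().export(str(path))


def extract_fo_candidates(
    fo_mesh: TriMesh,
    thickness_map: np.ndarray,
    la_reference: np.ndarray | None = None,
    superior: np.ndarray | None = None,
    posterior: np.ndarray | None = None,
) -> FOPatch:
    """Turn every FO mesh vertex into a candidate puncture site.

    Parameters
    ----------
    thickness_map : array
        Per-vertex septal thickness in mm, strictly positive.
    la_reference : 3-point, optional
        Any point on the LA side (typically the LA centroid).  Vertex normals
        are flipped so they point toward it — i.e. in the catheter insertion
        direction.  STL carries no canonical normal sense, so orientation
        must be anchored externally; without a reference the mesh's own
        winding is kept.
    superior, posterior : unit 3-vectors, optional
        In-plane anatomical frame; when given, each candidate is labelled
        with its quadrant (SP/IP/SA/IA) about the centroid.

    The centroid is the thinnest vertex (lowest index on ties).
    """
    thickness = np.asarray(thickness_map, dtype=float)
    if len(thickness) != fo_mesh.n_vertices:
        raise ValidationError(
            f"thickness map length {len(thickness)} != vertex count {fo_mesh.n_vertices}"
        )
    if np.any(thickness <= 0):
        raise ValidationError("thickness must be strictly positive")
    tm = fo_mesh.as_trimesh()
    normals = np.array(tm.vertex_normals, dtype=float)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    ci = int(np.argmin(thickness))  # argmin returns the lowest index on ties
    centroid = fo_mesh.vertices[ci]
    if la_reference is not None:
        toward_la = np.asarray(la_reference, dtype=float) - centroid
        # flip the whole patch at once so the field stays consistent
        if float(normals.mean(axis=0) @ toward_la) < 0:
            normals = -normals
    quadrant = None
    if superior is not None and posterior is not None:
        quadrant = np.array(
            [assign_quadrant(p, superior, posterior, centroid) for p in fo_mesh.vertices]
        )
    return FOPatch(
        points=fo_mesh.vertices.copy(),
        normals=normals,
        thickness=thickness,
        centroid=centroid,
        centroid_index=ci,
        quadrant=quadrant,
        superior=None if superior is None else np.asarray(superior, dtype=float),
        posterior=None if posterior is None else np.asarray(posterior, dtype=float),
    )


def assign_quadrant(
    point: np.ndarray,
    superior: np.ndarray,
    posterior: np.ndarray,
    centroid: np.ndarray,
) -> str:
    """Quadrant label (SP, IP, SA, IA) of a point about the FO centroid.

    The label combines the signs of the in-plane offsets along the superior
    and posterior axes; exact zero offsets resolve toward S and toward P.
    """
    superior = np.asarray(superior, dtype=float)
    posterior = np.asarray(posterior, dtype=float)
    for v in (superior, posterior):
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise ValidationError("frame axes must be unit vectors (tol 1e-9)")
    if abs(float(superior @ posterior)) > 1e-9:
        raise ValidationError("frame axes must be orthogonal (tol 1e-9)")
    offset = np.asarray(point, dtype=float) - np.asarray(centroid, dtype=float)
    s = float(offset @ superior)
    p = float(offset @ posterior)
    return ("S" if s >= 0 else "I") + ("P" if p >= 0 else "A")


def points_inside(mesh: TriMesh, points: np.ndarray, direction=None) -> np.ndarray:
    """Ray-parity inside test for a watertight mesh, vectorized.

    Casts one ray per query point along a fixed irrational direction (to
    dodge edge/vertex degeneracies on symmetric meshes) and counts
    Moller-Trumbore triangle crossings; odd parity means inside.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if direction is None:
        direction = np.array([0.57735027, 0.57735091, 0.57734963])
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    h = np.cross(d, e2)  # (F, 3)
    a = np.einsum("fj,fj->f", e1, h)
    valid = np.abs(a) > 1e-12
    v0, e1, e2, h, a = v0[valid], e1[valid], e2[valid], h[valid], a[valid]
    inside = np.empty(len(points), dtype=bool)
    eps = 1e-9
    chunk = max(1, int(4e6 // max(len(a), 1)))
    for i in range(0, len(points), chunk):
        s = points[i:i + chunk, None, :] - v0[None, :, :]  # (n, F, 3)
        u = np.einsum("nfj,fj->nf", s, h) / a
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("nfj,j->nf", q, d) / a
        t = np.einsum("nfj,fj->nf", q, e2) / a
        hits = (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
        inside[i:i + chunk] = (hits.sum(axis=1) % 2).astype(bool)
    return inside


def sample_la_interior(la_mesh: TriMesh, spacing: float = 2.5) -> LASamples:
    """Represent the LA cavity by a regular grid of interior points.

    An axis-aligned grid at ``spacing`` mm is laid over the bounding box and
    filtered by a ray-parity strictly-inside test.  A grid (rather than
    rejection sampling) keeps the discretization deterministic.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    tm = la_mesh.as_trimesh()
    if not tm.is_watertight:
        raise ValidationError("LA mesh must be watertight for interior sampling")
    lo, hi = tm.bounds
    axes = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
    if any(len(ax) == 0 for ax in axes):
        raise ResolutionError(
            f"spacing {spacing} mm too coarse for mesh extent {hi - lo}"
        )
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = points_inside(la_mesh, grid)
    points = grid[inside]
    if len(points) == 0:
        raise ResolutionError(
            f"no grid point at spacing {spacing} mm falls inside the mesh"
        )
    return LASamples(points=points, spacing=float(spacing))


def read_thickness_csv(path: str | Path, n_vertices: int | None = None) -> np.ndarray:
    """Read a per-vertex thickness map (columns vertex_index, thickness_mm)."""
    df = pd.read_csv(path)
    missing = {"vertex_index", "thickness_mm"} - set(df.columns)
    if missing:
        raise FormatError(f"thickness CSV missing columns: {sorted(missing)}")
    n = n_vertices if n_vertices is not None else int(df["vertex_index"].max()) + 1
    out = np.full(n, np.nan)
    out[df["vertex_index"].to_numpy()] = df["thickness_mm"].to_numpy()
    if np.isnan(out).any():
        raise ValidationError("thickness CSV does not cover every vertex")
    return out


def write_thickness_csv(thickness: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"vertex_index": np.arange(len(thickness)), "thickness_mm": thickness}
    ).to_csv(path, index=False)


def write_ply_scalar(mesh: TriMesh, scalar: np.ndarray, path: str | Path,
                     property_name: str = "quality") -> None:
    """Export an ASCII PLY with one float property per vertex (heatmap carrier)."""
    scalar = np.asarray(scalar, dtype=float)
    if len(scalar) != mesh.n_vertices:
        raise ValidationError("scalar length must equal vertex count")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"property float {property_name}\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, q in zip(mesh.vertices, scalar):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {q:.6f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
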