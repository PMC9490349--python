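"""Surface-scan I/O, tool orientation and the encompassing convex hull.

Tools are analysed in a standard frame: the long axis of the artefact runs
along Y, the active (damage-bearing) face points up (+Z), and six idealised
planes label the faces of the block — A (up, active), A2 (down), B/B2
(front/rear along Y) and C/C2 (left/right along X). All coordinates are in
millimetres.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import DegeneracyError, MalformedInputError, PairingError

PLANE_LABELS = ("A", "A2", "B", "B2", "C", "C2")

#: outward axis of each idealised plane in the oriented frame
PLANE_AXES = {
    "A": np.array([0.0, 0.0, 1.0]),
    "A2": np.array([0.0, 0.0, -1.0]),
    "B": np.array([0.0, 1.0, 0.0]),
    "B2": np.array([0.0, -1.0, 0.0]),
    "C": np.array([1.0, 0.0, 0.0]),
    "C2": np.array([-1.0, 0.0, 0.0]),
}

PIT_TABLE_COLUMNS = [
    "tool_id", "plane", "pit_id", "area_cm2", "length_mm", "width_mm",
    "depth_mm", "gradient", "roughness_mm", "dac_mm", "dae_mm",
    "pa_percent", "density_per_cm2", "n_pits",
]


@dataclass
class OrientedSurfaceModel:
    """A tool's 3D point set (mm), optionally triangulated and oriented."""

    tool_id: str
    points: np.ndarray                      # (N, 3) float64, mm
    faces: np.ndarray | None = None         # (M, 3) int triangle indices
    plane_assignment: dict[str, np.ndarray] = field(default_factory=dict)
    active_planes: list[str] = field(default_factory=list)
    oriented: bool = False
    units: str = "mm"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MalformedInputError("points must be an (N, 3) array")
        if self.points.shape[0] < 4:
            raise MalformedInputError("a surface model needs at least 4 points")
        if not np.all(np.isfinite(self.points)):
            raise MalformedInputError("non-finite coordinates in point set")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def active_plane_indices(self, plane: str = "A") -> np.ndarray:
        if plane not in self.plane_assignment:
            raise PairingError(f"plane {plane!r} has no assigned points")
        return self.plane_assignment[plane]

    def median_point_spacing(self, plane: str | None = "A") -> float:
        """Median nearest-neighbour distance, optionally within one plane."""
        pts = self.points
        if plane is not None and plane in self.plane_assignment:
            pts = self.points[self.plane_assignment[plane]]
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        return float(np.median(d[:, 1]))


@dataclass
class ConvexHullRef:
    """Encompassing convex hull of a model with signed-distance queries.

    Signed distance is negative for points inside/below the hull and zero on
    its surface.  For a point inside a convex polytope the distance to the
    boundary equals the largest (least negative) of its signed distances to
    the facet planes, so queries are exact and O(facets) per point.
    """

    model: OrientedSurfaceModel
    hull: ConvexHull

    @property
    def hull_vertices(self) -> np.ndarray:
        return self.hull.vertices

    @property
    def hull_facets(self) -> np.ndarray:
        return self.hull.simplices

    @property
    def volume(self) -> float:
        return float(self.hull.volume)

    @property
    def area(self) -> float:
        return float(self.hull.area)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        eq = self.hull.equations  # (F, 4): n·x + d = 0, n outward
        d = pts @ eq[:, :3].T + eq[:, 3]
        return d.max(axis=1)


def _strip_line_prefix(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _read_xyz(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise MalformedInputError(f"empty XYZ file: {path}")
    start = 0
    first = lines[0].replace(",", " ").split()
    # field-collected files sometimes carry a single header line
    if not all(_strip_line_prefix(t) for t in first):
        start = 1
    for ln in lines[start:]:
        toks = ln.replace(",", " ").split()
        if len(toks) < 3:
            raise MalformedInputError(f"XYZ row with <3 columns: {ln!r}")
        try:
            rows.append([float(t) for t in toks[:3]])
        except ValueError as exc:
            raise MalformedInputError(f"non-numeric XYZ row: {ln!r}") from exc
    return np.array(rows, dtype=float)


def read_surface(path: str | Path, format: str | None = None) -> OrientedSurfaceModel:
    """Read a PLY/OBJ/XYZ surface scan into an (unoriented) model.

    ``format`` defaults to the file extension.  XYZ accepts whitespace- or
    comma-delimited columns with an optional header line.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    tool_id = path.stem
    if fmt == "xyz":
        pts = _read_xyz(path)
        return OrientedSurfaceModel(tool_id=tool_id, points=pts)
    if fmt in ("ply", "obj"):
        mesh = trimesh.load(str(path), file_type=fmt, process=False)
        if isinstance(mesh, trimesh.points.PointCloud):
            pts, faces = np.asarray(mesh.vertices, dtype=float), None
        else:
            pts = np.asarray(mesh.vertices, dtype=float)
            faces = np.asarray(mesh.faces, dtype=np.int64) if len(mesh.faces) else None
        if pts.shape[0] < 4:
            raise MalformedInputError(f"{path}: fewer than 4 points")
        return OrientedSurfaceModel(tool_id=tool_id, points=pts, faces=faces)
    raise MalformedInputError(f"unsupported surface format: {fmt!r}")


def write_surface(model: OrientedSurfaceModel, path: str | Path,
                  format: str | None = None) -> Path:
    """Write a model as PLY (ASCII, double precision), OBJ or XYZ.

    Coordinates are written with 17 significant digits so that a read-back
    reproduces the float64 values bitwise.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    pts = model.points
    buf = io.StringIO()
    if fmt == "xyz":
        for p in pts:
            buf.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    elif fmt == "obj":
        for p in pts:
            buf.write(f"v {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        if model.faces is not None:
            for f in model.faces:
                buf.write(f"f {f[0]+1} {f[1]+1} {f[2]+1}\n")
    elif fmt == "ply":
        nf = 0 if model.faces is None else len(model.faces)
        buf.write("ply\nformat ascii 1.0\n")
        buf.write(f"element vertex {len(pts)}\n")
        buf.write("property double x\nproperty double y\nproperty double z\n")
        buf.write(f"element face {nf}\n")
        buf.write("property list uchar int vertex_indices\nend_header\n")
        for p in pts:
            buf.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        if model.faces is not None:
            for f in model.faces:
                buf.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:
        raise MalformedInputError(f"unsupported surface format: {fmt!r}")
    path.write_text(buf.getvalue())
    return path


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the point covariance, eigenvalues descending."""
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred / max(len(points) - 1, 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def _check_nondegenerate(points: np.ndarray) -> None:
    w, _ = _principal_axes(points)
    if w[0] <= 0 or w[-1] / w[0] < 1e-18:
        raise DegeneracyError("point cloud is collinear or coplanar")


def estimate_point_normals(points: np.ndarray, k: int = 12) -> np.ndarray:
    """Unoriented per-point normals from local covariance (smallest axis)."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=min(k, len(points)))
    local = points[idx]                             # (N, k, 3)
    local = local - local.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", local, local)   # batched 3x3 covariances
    _, vecs = np.linalg.eigh(cov)                   # ascending eigenvalues
    return vecs[:, :, 0]


def _assign_planes(points: np.ndarray, angular_tol_deg: float = 30.0,
                   normals: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Assign points to the six idealised planes of the oriented frame.

    A point belongs to the plane whose outward axis its (unoriented) local
    normal matches within the angular tolerance; opposite faces of the same
    axis are separated by position relative to the box centre. Edge/corner
    points beyond the tolerance stay unassigned.
    """
    if normals is None:
        normals = estimate_point_normals(points)
    cos_tol = np.cos(np.radians(angular_tol_deg))
    centre = (points.min(axis=0) + points.max(axis=0)) / 2.0
    rel = points - centre
    assignment: dict[str, list[int]] = {}
    # axis index for each pair: (A, A2)->z, (B, B2)->y, (C, C2)->x
    axis_of = {("A", "A2"): 2, ("B", "B2"): 1, ("C", "C2"): 0}
    align = np.abs(normals)  # |cos| against each coordinate axis
    best_axis = np.argmax(align, axis=1)
    for (pos_label, neg_label), ax in axis_of.items():
        on_axis = (align[:, ax] >= cos_tol) & (best_axis == ax)
        pos = np.where(on_axis & (rel[:, ax] >= 0))[0]
        neg = np.where(on_axis & (rel[:, ax] < 0))[0]
        if len(pos):
            assignment[pos_label] = pos
        if len(neg):
            assignment[neg_label] = neg
    return {k: np.asarray(v, dtype=np.int64) for k, v in assignment.items()}


def _level_active_plane(points: np.ndarray) -> np.ndarray:
    """Small corrective rotation that levels the upward flat face.

    Principal axes of a worn tool are skewed by the carved damage, leaving
    the active face tilted by a few degrees — enough for a slope to mimic a
    depression at the downhill edge of a TPI neighbourhood.  A trimmed
    least-squares plane through the top-slab points (pit points fall below
    the fit and are discarded once) gives the residual tilt to remove.
    """
    z = points[:, 2]
    thickness = z.max() - z.min()
    top = points[z > z.max() - 0.2 * thickness]
    if len(top) < 10:
        return points
    for _ in range(2):
        A = np.column_stack([top[:, 0], top[:, 1], np.ones(len(top))])
        coef, *_ = np.linalg.lstsq(A, top[:, 2], rcond=None)
        resid = top[:, 2] - A @ coef
        mad = np.median(np.abs(resid - np.median(resid))) or 1e-12
        keep = resid > np.median(resid) - 3.0 * mad   # drop pit points only
        if keep.all():
            break
        top = top[keep]
    a, b = coef[0], coef[1]
    normal = np.array([-a, -b, 1.0])
    normal /= np.linalg.norm(normal)
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, zhat)
    s, c = np.linalg.norm(v), float(normal @ zhat)
    if s < 1e-12:
        return points
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))
    return points @ R.T


def orient_model(model: OrientedSurfaceModel,
                 up_hint: np.ndarray | None = None,
                 angular_tol_deg: float = 30.0) -> OrientedSurfaceModel:
    """Rigidly rotate a model into the standard analysis frame.

    The longest extent of the cloud ends up on Y, the shortest (the slab
    thickness) on Z, and the active face points to +Z.  When ``up_hint`` is
    given the +Z side is the one it indicates; otherwise the side whose
    extreme slab holds fewer points faces up: concave damage pulls surface
    points below the face plane, thinning the damaged side's outermost slab
    (a stand-in for the field protocol of facing the visibly damaged
    surface upward, which a program cannot see).
    """
    _check_nondegenerate(model.points)
    w, axes = _principal_axes(model.points)

    centred = model.points - model.points.mean(axis=0)
    proj = centred @ axes
    extents = proj.max(axis=0) - proj.min(axis=0)
    # X <- middle extent, Y <- largest, Z <- smallest
    order = np.argsort(extents)           # ascending
    col_for = [order[1], order[2], order[0]]
    R = axes[:, col_for]                  # columns = new x, y, z in old frame

    # deterministic signs: favour the identity when already oriented
    for c in range(3):
        if R[c, c] < 0:
            R[:, c] *= -1
    if np.linalg.det(R) < 0:
        R[:, 0] *= -1

    new_pts = centred @ R
    z = new_pts[:, 2]
    if up_hint is not None:
        hint = np.asarray(up_hint, dtype=float)
        if float(hint @ R[:, 2]) < 0:
            new_pts = new_pts * np.array([-1.0, 1.0, -1.0])
    else:
        # point counts in the two extreme z-slabs: the damaged face's slab
        # is thinner because pit points fall below the face plane
        thickness = z.max() - z.min()
        top = np.sum(z > z.max() - 0.1 * thickness)
        bot = np.sum(z < z.min() + 0.1 * thickness)
        if bot < top:
            new_pts = new_pts * np.array([-1.0, 1.0, -1.0])

    new_pts = _level_active_plane(new_pts)

    oriented = OrientedSurfaceModel(
        tool_id=model.tool_id, points=new_pts, faces=model.faces,
        oriented=True,
    )
    oriented.plane_assignment = _assign_planes(new_pts, angular_tol_deg)
    oriented.active_planes = ["A"]
    if "A" not in oriented.plane_assignment:
        # tolerant fallback: top decile of z counts as the active face
        zc = oriented.points[:, 2]
        thickness = zc.max() - zc.min()
        oriented.plane_assignment["A"] = np.where(
            zc > zc.max() - 0.1 * max(thickness, 1e-12))[0]
    return oriented


def compute_convex_hull(model: OrientedSurfaceModel) -> ConvexHullRef:
    """Encompassing convex hull used as the depth reference surface."""
    _check_nondegenerate(model.points)
    try:
        hull = ConvexHull(model.points)
    except QhullError as exc:
        raise DegeneracyError(f"convex hull failed: {exc}") from exc
    return ConvexHullRef(model=model, hull=hull)


def write_pit_table(pits, summary, path: str | Path) -> Path:
    """Write per-pit rows plus one per-surface summary row as CSV.

    ``pits`` is a sequence of PitRegion-like objects; ``summary`` a
    PlanformSummary-like object.  Columns and their order are fixed
    (see PIT_TABLE_COLUMNS); areas are reported in cm², lengths in mm.
    """
    rows = []
    for pit in pits:
        if summary is not None and pit.tool_id != summary.tool_id:
            raise PairingError(
                f"pit {pit.pit_id} belongs to {pit.tool_id!r}, "
                f"summary to {summary.tool_id!r}")
        rows.append({
            "tool_id": pit.tool_id, "plane": pit.plane, "pit_id": pit.pit_id,
            "area_cm2": pit.area_cm2, "length_mm": pit.length_mm,
            "width_mm": pit.width_mm, "depth_mm": pit.depth_mm,
            "gradient": pit.gradient, "roughness_mm": pit.roughness_mm,
            "dac_mm": pit.dac_mm, "dae_mm": pit.dae_mm,
            "pa_percent": np.nan, "density_per_cm2": np.nan, "n_pits": np.nan,
        })
    if summary is not None:
        rows.append({
            "tool_id": summary.tool_id, "plane": summary.plane,
            "pit_id": "SURFACE", "area_cm2": summary.surface_area_cm2,
            "length_mm": np.nan, "width_mm": np.nan, "depth_mm": np.nan,
            "gradient": np.nan, "roughness_mm": np.nan,
            "dac_mm": summary.dac_mean_mm, "dae_mm": summary.dae_mean_mm,
            "pa_percent": summary.pa_percent,
            "density_per_cm2": summary.density_per_cm2,
            "n_pits": summary.n_pits,
        })
    frame = pd.DataFrame(rows, columns=PIT_TABLE_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
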