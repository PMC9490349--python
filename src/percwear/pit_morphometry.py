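"""Pit detection and 3D morphometrics on the active surface.

Percussive pits are found as depressions of a topographic position index
(TPI): each point's elevation minus the mean elevation of its planimetric
neighbourhood (default radius 20 mm).  Contiguous sub-threshold points form
candidate regions; regions shorter than the 10 mm discrete-pit criterion are
discarded.  Each surviving pit gets three surface morphometrics:

* depth — signed deviation from the encompassing convex hull (negative =
  below the hull), both the mean over member points and the deepest point;
* gradient — mean local slope, the rise-over-run ratio of planes fitted in a
  small neighbourhood of each member point;
* roughness — mean absolute deviation of each member point from the
  least-squares plane of its 0.5 mm neighbourhood window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import InsufficientSupportError, PairingError, ParameterError
from .surface_io import ConvexHullRef, OrientedSurfaceModel

K_MIN_NEIGHBOURS = 5   # below this the TPI is undefined, not extrapolated


@dataclass
class TPIField:
    """Per-point topographic position index on the active plane (mm)."""

    model_id: str
    point_index: np.ndarray     # indices into the parent model's points
    values: np.ndarray          # TPI, NaN where undefined
    radius_mm: float

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class PitRegion:
    """One contiguous detected depression with its morphometrics."""

    tool_id: str
    pit_id: str
    plane: str
    member_indices: np.ndarray          # indices into the parent model
    centroid_xy: tuple[float, float]
    # 3D morphometrics (filled by the measure_* functions)
    depth_mm: float = np.nan            # mean member deviation from hull
    depth_max_mm: float = np.nan        # deepest member deviation
    gradient: float = np.nan
    roughness_mm: float = np.nan
    # 2D planform (filled by planform.pit_planform_metrics)
    area_cm2: float = np.nan
    length_mm: float = np.nan
    width_mm: float = np.nan
    dac_mm: float = np.nan
    dae_mm: float = np.nan
    extras: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return int(len(self.member_indices))


def compute_tpi(model: OrientedSurfaceModel, radius: float = 20.0,
                plane: str = "A", k_min: int = K_MIN_NEIGHBOURS) -> TPIField:
    """Topographic position index over one plane's points.

    TPI_i = z_i − mean{z_j : planimetric distance(i, j) ≤ radius, j ≠ i}.
    Points with fewer than ``k_min`` in-radius neighbours get NaN. Adding a
    constant to all elevations leaves the field unchanged.
    """
    if radius <= 0:
        raise ParameterError("TPI radius must be positive")
    idx = model.active_plane_indices(plane)
    pts = model.points[idx]
    xy, z = pts[:, :2], pts[:, 2]
    tree = cKDTree(xy)
    values = np.full(len(idx), np.nan)
    neighbours = tree.query_ball_point(xy, r=radius)
    for i, nb in enumerate(neighbours):
        nb = [j for j in nb if j != i]
        if len(nb) < k_min:
            continue
        values[i] = z[i] - z[nb].mean()
    return TPIField(model_id=model.tool_id, point_index=idx,
                    values=values, radius_mm=radius)


def _oriented_bbox_length(xy: np.ndarray) -> float:
    """Length (longer side) of the minimum-area rotated rectangle."""
    from shapely import MultiPoint
    mp = MultiPoint(xy)
    rect = mp.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":        # collinear/degenerate
        return float(rect.length)
    coords = np.asarray(rect.exterior.coords)[:4]
    s1 = float(np.linalg.norm(coords[1] - coords[0]))
    s2 = float(np.linalg.norm(coords[2] - coords[1]))
    return max(s1, s2)


def default_depression_threshold(tpi: TPIField,
                                 floor_mm: float = 0.3) -> float:
    """Noise-adaptive TPI threshold: max(floor, 3×MAD of defined TPI)."""
    v = tpi.values[tpi.defined]
    if len(v) == 0:
        return floor_mm
    mad = float(np.median(np.abs(v - np.median(v))))
    return max(floor_mm, 3.0 * mad)


def detect_pit_regions(tpi: TPIField, model: OrientedSurfaceModel,
                       threshold: float | None = None,
                       linkage_radius: float | None = None,
                       min_length: float = 10.0,
                       plane: str = "A") -> list[PitRegion]:
    """Segment contiguous TPI depressions into discrete pit regions.

    Points with TPI < −threshold form the depression mask; connected
    components of the mask under ``linkage_radius`` adjacency (default 4×
    the median nearest-neighbour spacing — random-geometric-graph
    connectivity of uniformly sampled scans needs a multiple of the mean
    spacing, while grid-like scans connect at 2×) are candidates, and
    candidates
    whose oriented-bounding-box length falls below ``min_length`` (the
    10 mm discrete-pit size criterion) are dropped.  Returned regions are
    disjoint and maximal by construction of connected components.
    """
    if tpi.model_id != model.tool_id:
        raise PairingError("TPI field was computed on a different model")
    if threshold is None:
        threshold = default_depression_threshold(tpi)
    if threshold <= 0 or min_length <= 0:
        raise ParameterError("threshold and min_length must be positive")

    idx = tpi.point_index
    if len(idx) == 0:
        return []
    pts = model.points[idx]
    if linkage_radius is None:
        tree_all = cKDTree(pts[:, :2])
        d, _ = tree_all.query(pts[:, :2], k=2)
        linkage_radius = 4.0 * float(np.median(d[:, 1]))
    if linkage_radius <= 0:
        raise ParameterError("linkage_radius must be positive")

    mask = tpi.defined & (tpi.values < -threshold)
    cand = np.where(mask)[0]
    if len(cand) == 0:
        return []
    sub = pts[cand][:, :2]
    tree = cKDTree(sub)
    pairs = tree.query_pairs(r=linkage_radius, output_type="ndarray")
    n = len(cand)
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)

    regions: list[PitRegion] = []
    for comp in range(n_comp):
        members_local = cand[labels == comp]
        members = idx[members_local]
        xy = model.points[members][:, :2]
        if len(members) < 3:
            continue
        if _oriented_bbox_length(xy) < min_length:
            continue
        centroid = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
        regions.append(PitRegion(
            tool_id=model.tool_id, pit_id="", plane=plane,
            member_indices=members, centroid_xy=centroid))
    # deterministic ids ordered along the tool's long axis, then across
    regions.sort(key=lambda r: (r.centroid_xy[1], r.centroid_xy[0]))
    for k, r in enumerate(regions, start=1):
        r.pit_id = f"{model.tool_id}-P{k:02d}"
    return regions


def measure_pit_depth(region: PitRegion, hull: ConvexHullRef,
                      model: OrientedSurfaceModel) -> float:
    """Depth of a pit as signed deviation from the encompassing hull.

    Fills ``depth_mm`` (mean member deviation, the primary value) and
    ``depth_max_mm`` (the deepest single member) on the region and returns
    the mean.  Negative values lie below the hull.
    """
    if hull.model.tool_id != model.tool_id or region.tool_id != model.tool_id:
        raise PairingError("region/hull/model belong to different tools")
    if region.n_members == 0:
        raise ParameterError("empty pit region")
    d = hull.signed_distance(model.points[region.member_indices])
    region.depth_mm = float(d.mean())
    region.depth_max_mm = float(d.min())
    region.extras["member_hull_distances"] = d
    return region.depth_mm


def _local_plane_slopes(points: np.ndarray, query: np.ndarray,
                        radius: float, min_neighbours: int) -> np.ndarray:
    """Slope (rise/run) of least-squares planes fitted around query points."""
    tree = cKDTree(points[:, :2])
    slopes = np.full(len(query), np.nan)
    for i, q in enumerate(query):
        nb = tree.query_ball_point(q[:2], r=radius)
        if len(nb) < min_neighbours:
            continue
        local = points[nb]
        xy = local[:, :2] - local[:, :2].mean(axis=0)
        z = local[:, 2] - local[:, 2].mean()
        # z ≈ a·x + b·y ; slope = |(a, b)| = tan(dip angle)
        g, *_ = np.linalg.lstsq(xy, z, rcond=None)
        slopes[i] = float(np.hypot(g[0], g[1]))
    return slopes


def measure_pit_gradient(region: PitRegion, model: OrientedSurfaceModel,
                         fit_radius: float = 2.0) -> float:
    """Mean local slope (elevation change over planimetric distance)."""
    if region.tool_id != model.tool_id:
        raise PairingError("region belongs to a different model")
    if fit_radius <= 0:
        raise ParameterError("fit_radius must be positive")
    members = model.points[region.member_indices]
    # fit only against points of the region's own plane: other faces of the
    # block share the same planimetric footprint and would wreck the fits
    if region.plane in model.plane_assignment:
        candidates = model.points[model.plane_assignment[region.plane]]
    else:
        candidates = model.points
    slopes = _local_plane_slopes(candidates, members, fit_radius,
                                 min_neighbours=3)
    ok = ~np.isnan(slopes)
    if not ok.any():
        raise InsufficientSupportError(
            "no member point has 3 in-radius neighbours for plane fitting")
    region.gradient = float(slopes[ok].mean())
    return region.gradient


def measure_pit_roughness(region: PitRegion, model: OrientedSurfaceModel,
                          window: float = 0.5) -> float:
    """Mean absolute deviation from the local-window least-squares plane."""
    if region.tool_id != model.tool_id:
        raise PairingError("region belongs to a different model")
    if window <= 0:
        raise ParameterError("window must be positive")
    pts = model.points
    tree = cKDTree(pts)
    members = region.member_indices
    vals = []
    for m in members:
        nb = tree.query_ball_point(pts[m], r=window)
        if len(nb) < 4:
            continue
        local = pts[nb]
        c = local.mean(axis=0)
        _, _, vt = np.linalg.svd(local - c, full_matrices=False)
        normal = vt[-1]
        vals.append(abs(float((pts[m] - c) @ normal)))
    if not vals:
        raise InsufficientSupportError(
            f"window {window} mm captures <4 points everywhere; "
            "scan density too low")
    region.roughness_mm = float(np.mean(vals))
    return region.roughness_mm


def measure_regions(regions: list[PitRegion], model: OrientedSurfaceModel,
                    hull: ConvexHullRef, fit_radius: float = 2.0,
                    roughness_window: float = 0.5,
                    skip_undefined: bool = True) -> list[PitRegion]:
    """Run all three 3D morphometrics over a list of regions in place."""
    for r in regions:
        measure_pit_depth(r, hull, model)
        try:
            measure_pit_gradient(r, model, fit_radius=fit_radius)
            measure_pit_roughness(r, model, window=roughness_window)
        except InsufficientSupportError:
            if not skip_undefined:
                raise
    return regions
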