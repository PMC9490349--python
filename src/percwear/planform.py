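"""2D planform quantification of active surfaces and pits.

The oriented active surface is projected to the XY plane; its outline is an
alpha shape of the projected points.  From the outline and the pit polygons
come the spatial damage measures: PA (percent of the active surface covered
by pitting), D (pits per cm²), DAC (distance from each pit centre to the
surface centre) and DAE (distance from each pit centre to the nearest edge).
Lengths are mm, areas cm².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .errors import DegeneracyError, ParameterError
from .pit_morphometry import PitRegion
from .surface_io import OrientedSurfaceModel

MM2_PER_CM2 = 100.0


@dataclass
class ActiveSurfaceOutline:
    """Planform boundary polygon of one active surface."""

    tool_id: str
    plane: str
    polygon: Polygon            # coordinates in mm

    @property
    def area_cm2(self) -> float:
        return float(self.polygon.area) / MM2_PER_CM2

    @property
    def centroid_xy(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (float(c.x), float(c.y))


@dataclass
class PlanformSummary:
    """Per active surface: pit coverage, density and position statistics."""

    tool_id: str
    plane: str
    n_pits: int
    surface_area_cm2: float
    pa_percent: float
    density_per_cm2: float
    dac_min_mm: float = np.nan
    dac_mean_mm: float = np.nan
    dac_max_mm: float = np.nan
    dae_min_mm: float = np.nan
    dae_mean_mm: float = np.nan
    dae_max_mm: float = np.nan
    dae_per_pit: dict[str, float] = field(default_factory=dict)


def alpha_shape(xy: np.ndarray, alpha: float) -> Polygon:
    """Alpha shape of 2D points: union of Delaunay triangles whose
    circumradius is at most ``alpha``.  ``alpha = inf`` gives the convex
    hull.  Result is the largest polygon when the union is disconnected.
    """
    xy = np.asarray(xy, dtype=float)
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    if len(xy) < 3:
        raise DegeneracyError("alpha shape needs at least 3 points")
    if not np.isfinite(alpha):
        hull = MultiPoint(xy).convex_hull
        if hull.geom_type != "Polygon":
            raise DegeneracyError("points are collinear")
        return hull
    try:
        tri = Delaunay(xy)
    except QhullError as exc:
        raise DegeneracyError(f"degenerate 2D projection: {exc}") from exc
    simplices = tri.simplices
    a = xy[simplices[:, 0]]
    b = xy[simplices[:, 1]]
    c = xy[simplices[:, 2]]
    # circumradius R = abc / (4 · area)
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                   - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = (la * lb * lc) / (2.0 * area2)
    keep = simplices[(area2 > 0) & (circumradius <= alpha)]
    if len(keep) == 0:
        raise DegeneracyError("alpha too small: no triangle survives")
    polys = shapely.polygons(xy[keep])
    merged = unary_union(polys)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    if merged.geom_type != "Polygon" or merged.area <= 0:
        raise DegeneracyError("alpha shape collapsed to a degenerate geometry")
    return Polygon(merged.exterior)   # fill interior holes: outline only


def extract_active_outline(model: OrientedSurfaceModel, plane: str = "A",
                           alpha: float | None = None) -> ActiveSurfaceOutline:
    """Outline polygon of one plane's XY projection via an alpha shape.

    Default alpha is 5× the plane's median point spacing (outlines are
    large and smooth compared to pit polygons).
    """
    idx = model.active_plane_indices(plane)
    if len(idx) < 3:
        raise DegeneracyError(f"plane {plane!r} has fewer than 3 points")
    xy = model.points[idx][:, :2]
    if alpha is None:
        alpha = 5.0 * model.median_point_spacing(plane)
    poly = alpha_shape(xy, alpha)
    return ActiveSurfaceOutline(tool_id=model.tool_id, plane=plane,
                                polygon=poly)


def min_area_rect_dims(polygon: Polygon) -> tuple[float, float]:
    """(length, width) of the minimum-area rotated rectangle, length ≥ width."""
    rect = polygon.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        raise DegeneracyError("degenerate shape has no bounding rectangle")
    coords = np.asarray(rect.exterior.coords)[:4]
    s1 = float(np.linalg.norm(coords[1] - coords[0]))
    s2 = float(np.linalg.norm(coords[2] - coords[1]))
    return (max(s1, s2), min(s1, s2))


def pit_planform_polygon(region: PitRegion, model: OrientedSurfaceModel,
                         alpha: float | None = None) -> Polygon:
    """Planform polygon of a pit: alpha shape of member XY (default alpha =
    4× the median point spacing — tight enough to keep pit concavity, loose
    enough that uniformly sampled interiors do not shred into fragments)."""
    xy = model.points[region.member_indices][:, :2]
    if len(xy) < 3:
        raise DegeneracyError("pit region has fewer than 3 members")
    if alpha is None:
        alpha = 4.0 * model.median_point_spacing(region.plane)
    return alpha_shape(xy, alpha)


def pit_planform_metrics(region: PitRegion, model: OrientedSurfaceModel,
                         alpha: float | None = None,
                         ) -> tuple[float, float, float, tuple[float, float]]:
    """Fill area (cm²), oriented-bbox length/width (mm) and centroid of a pit.

    Returns (area_cm2, length_mm, width_mm, centroid_xy) and stores them on
    the region.  The pit polygon's centroid replaces the raw member-point
    mean as the pit's geometric centre.
    """
    poly = pit_planform_polygon(region, model, alpha)
    length, width = min_area_rect_dims(poly)
    region.area_cm2 = float(poly.area) / MM2_PER_CM2
    region.length_mm, region.width_mm = length, width
    c = poly.centroid
    region.centroid_xy = (float(c.x), float(c.y))
    region.extras["polygon"] = poly
    return region.area_cm2, length, width, region.centroid_xy


def surface_damage_summary(pits: list[PitRegion],
                           outline: ActiveSurfaceOutline) -> PlanformSummary:
    """PA and D for one active surface.

    PA is the area of the union of pit polygons clipped to the outline as a
    percentage of the outline area (overlapping pits are not double
    counted); D is the pit count per cm² of outline.
    """
    area = outline.area_cm2
    if area <= 0:
        raise DegeneracyError("outline has zero area")
    n = len(pits)
    if n == 0:
        return PlanformSummary(tool_id=outline.tool_id, plane=outline.plane,
                               n_pits=0, surface_area_cm2=area,
                               pa_percent=0.0, density_per_cm2=0.0)
    polys = [p.extras.get("polygon") for p in pits]
    if any(poly is None for poly in polys):
        raise ParameterError("run pit_planform_metrics before the summary")
    union = unary_union(polys).intersection(outline.polygon)
    pa = 100.0 * float(union.area) / float(outline.polygon.area)
    return PlanformSummary(tool_id=outline.tool_id, plane=outline.plane,
                           n_pits=n, surface_area_cm2=area,
                           pa_percent=pa, density_per_cm2=n / area)


def pit_position_metrics(pits: list[PitRegion],
                         outline: ActiveSurfaceOutline,
                         summary: PlanformSummary | None = None,
                         ) -> PlanformSummary:
    """DAC (pit centre to surface centre) and DAE (pit centre to nearest
    edge) statistics, written into a PlanformSummary."""
    if summary is None:
        summary = surface_damage_summary(pits, outline)
    if not pits:
        return summary
    cx, cy = outline.centroid_xy
    boundary = outline.polygon.exterior
    dac, dae = [], {}
    for p in pits:
        px, py = p.centroid_xy
        dac.append(float(np.hypot(px - cx, py - cy)))
        d_edge = float(boundary.distance(Point(px, py)))
        dae[p.pit_id] = d_edge
        p.dac_mm, p.dae_mm = dac[-1], d_edge
    dac = np.asarray(dac)
    dae_vals = np.asarray(list(dae.values()))
    summary.dac_min_mm = float(dac.min())
    summary.dac_mean_mm = float(dac.mean())
    summary.dac_max_mm = float(dac.max())
    summary.dae_min_mm = float(dae_vals.min())
    summary.dae_mean_mm = float(dae_vals.mean())
    summary.dae_max_mm = float(dae_vals.max())
    summary.dae_per_pit = dae
    return summary


def summarize_plane(model: OrientedSurfaceModel, pits: list[PitRegion],
                    plane: str = "A", outline_alpha: float | None = None,
                    pit_alpha: float | None = None) -> PlanformSummary:
    """Convenience: outline + per-pit planform + PA/D + DAC/DAE in one call."""
    outline = extract_active_outline(model, plane, alpha=outline_alpha)
    for p in pits:
        pit_planform_metrics(p, model, alpha=pit_alpha)
    summary = surface_damage_summary(pits, outline)
    return pit_position_metrics(pits, outline, summary)


def export_geojson(outline: ActiveSurfaceOutline, pits: list[PitRegion],
                   path: str | Path) -> Path:
    """Write outline and pit polygons (planar mm coordinates) as GeoJSON."""
    feats = [{
        "type": "Feature",
        "properties": {"kind": "outline", "tool_id": outline.tool_id,
                       "plane": outline.plane},
        "geometry": json.loads(shapely.to_geojson(outline.polygon)),
    }]
    for p in pits:
        poly = p.extras.get("polygon")
        if poly is None:
            continue
        feats.append({
            "type": "Feature",
            "properties": {"kind": "pit", "tool_id": p.tool_id,
                           "pit_id": p.pit_id},
            "geometry": json.loads(shapely.to_geojson(poly)),
        })
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection",
                                "features": feats}))
    return path
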