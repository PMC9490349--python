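"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from percwear.surface_io import OrientedSurfaceModel


def grid_points(x_half: float, y_half: float, spacing: float,
                z: float = 0.0) -> np.ndarray:
    """Regular (N, 3) grid on [-x_half, x_half] x [-y_half, y_half] at z."""
    xs = np.arange(-x_half, x_half + spacing / 2, spacing)
    ys = np.arange(-y_half, y_half + spacing / 2, spacing)
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel(),
                           np.full(X.size, float(z))])
    return pts


def plane_model(points: np.ndarray, tool_id: str = "T") -> OrientedSurfaceModel:
    """Model whose plane A is exactly the given points (no orientation)."""
    model = OrientedSurfaceModel(tool_id=tool_id, points=np.asarray(points, float),
                                 oriented=True)
    model.plane_assignment = {"A": np.arange(len(points))}
    model.active_planes = ["A"]
    return model


def cap_dz(r: np.ndarray, radius: float, depth: float) -> np.ndarray:
    """Spherical-cap depression depth at planimetric distance r (test-side
    construction of the ground-truth pit shape)."""
    r = np.asarray(r, dtype=float)
    R = (radius * radius + depth * depth) / (2.0 * depth)
    dz = np.zeros_like(r)
    inside = r < radius
    dz[inside] = np.sqrt(R * R - r[inside] ** 2) - (R - depth)
    return dz


def box_model(top: np.ndarray, x_half: float, y_half: float,
              thickness: float, tool_id: str = "T") -> OrientedSurfaceModel:
    """Model of a slab: given top-face points (plane A) plus the 4 bottom
    corners so the convex hull closes below the top face."""
    bottom = np.array([[sx * x_half, sy * y_half, -thickness]
                       for sx in (-1, 1) for sy in (-1, 1)])
    pts = np.vstack([top, bottom])
    model = OrientedSurfaceModel(tool_id=tool_id, points=pts, oriented=True)
    model.plane_assignment = {"A": np.arange(len(top))}
    model.active_planes = ["A"]
    return model


def tpi_bruteforce(xy: np.ndarray, z: np.ndarray, radius: float,
                   k_min: int = 5) -> np.ndarray:
    """O(N^2) reference TPI: all pairwise planimetric distances explicitly."""
    n = len(z)
    out = np.full(n, np.nan)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    for i in range(n):
        nb = np.where((d[i] <= radius) & (np.arange(n) != i))[0]
        if len(nb) >= k_min:
            out[i] = z[i] - z[nb].mean()
    return out


def rect_min_area_bruteforce(xy: np.ndarray) -> tuple[float, float]:
    """Rotating-calipers oracle: sweep hull-edge orientations, return the
    (length, width) of the smallest-area enclosing rectangle."""
    from scipy.spatial import ConvexHull
    hull = ConvexHull(xy)
    pts = xy[hull.vertices]
    best = None
    n = len(pts)
    for i in range(n):
        e = pts[(i + 1) % n] - pts[i]
        e = e / np.linalg.norm(e)
        u = np.array([e[0], e[1]])
        v = np.array([-e[1], e[0]])
        pu = xy @ u
        pv = xy @ v
        s1, s2 = pu.max() - pu.min(), pv.max() - pv.min()
        area = s1 * s2
        if best is None or area < best[0]:
            best = (area, max(s1, s2), min(s1, s2))
    return best[1], best[2]


@pytest.fixture(scope="session")
def reference_records():
    from percwear.synthetic import load_djouroutou_tables
    return load_djouroutou_tables()


@pytest.fixture(scope="session")
def reference_frame(reference_records):
    from percwear.synthetic import records_to_frame
    return records_to_frame(reference_records)
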