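"""pit_morphometry: TPI, detection, depth, gradient, roughness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from percwear.errors import PairingError, ParameterError
from percwear.pit_morphometry import (
    compute_tpi,
    default_depression_threshold,
    detect_pit_regions,
    measure_pit_depth,
    measure_pit_gradient,
    measure_pit_roughness,
)
from percwear.surface_io import compute_convex_hull
from conftest import (
    box_model,
    cap_dz,
    grid_points,
    plane_model,
    tpi_bruteforce,
)


def pitted_grid(spacing=2.0, x_half=60.0, y_half=90.0, pits=(),
                noise_sd=0.0, seed=0, z0=0.0):
    """Grid plane with spherical-cap pits carved in (test-side construction)."""
    pts = grid_points(x_half, y_half, spacing, z=z0)
    for (cx, cy, radius, depth) in pits:
        r = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        pts[:, 2] -= cap_dz(r, radius, depth)
    if noise_sd:
        pts[:, 2] += np.random.default_rng(seed).normal(0, noise_sd, len(pts))
    return pts


# ----------------------------------------------------------------- TPI

def test_tpi_flat_plane_is_zero():
    model = plane_model(grid_points(30, 30, 5.0, z=7.0))
    tpi = compute_tpi(model, radius=20.0)
    assert tpi.defined.all()
    np.testing.assert_allclose(tpi.values, 0.0, atol=1e-12)


def test_tpi_single_depressed_point_exact():
    """3x3 grid, centre 1 mm below: TPI(centre) = -1 exactly."""
    pts = grid_points(5, 5, 5.0, z=0.0)       # 3x3, spacing 5
    centre = np.where((pts[:, 0] == 0) & (pts[:, 1] == 0))[0][0]
    pts[centre, 2] = -1.0
    tpi = compute_tpi(plane_model(pts), radius=20.0)
    assert tpi.values[centre] == pytest.approx(-1.0, abs=1e-12)
    # every neighbour sees the centre as 1/8 of its neighbourhood mean
    others = np.arange(9) != centre
    np.testing.assert_allclose(tpi.values[others], 1.0 / 8.0, atol=1e-12)


def test_tpi_matches_bruteforce_oracle():
    pts = pitted_grid(spacing=3.0, x_half=30, y_half=30,
                      pits=[(0, 0, 12, 4)], noise_sd=0.2, seed=1)
    model = plane_model(pts)
    tpi = compute_tpi(model, radius=10.0)
    oracle = tpi_bruteforce(pts[:, :2], pts[:, 2], radius=10.0)
    np.testing.assert_allclose(tpi.values, oracle, atol=1e-12)


def test_tpi_kmin_gives_nan():
    """Sparse corner points with <5 in-radius neighbours are undefined."""
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                    [100, 100, 0.0]])
    tpi = compute_tpi(plane_model(pts), radius=5.0)
    assert np.isnan(tpi.values).all()          # nobody has 5 neighbours


@settings(max_examples=20, deadline=None)
@given(shift=st.floats(-1e4, 1e4, allow_nan=False))
def test_tpi_shift_invariance(shift):
    pts = pitted_grid(spacing=4.0, x_half=24, y_half=24,
                      pits=[(0, 0, 10, 3)], noise_sd=0.1, seed=2)
    base = compute_tpi(plane_model(pts), radius=12.0).values
    shifted = pts.copy()
    shifted[:, 2] += shift
    moved = compute_tpi(plane_model(shifted), radius=12.0).values
    np.testing.assert_allclose(moved, base, atol=1e-9)


def test_tpi_bad_radius():
    with pytest.raises(ParameterError):
        compute_tpi(plane_model(grid_points(10, 10, 2.0)), radius=0.0)


# ------------------------------------------------------------- detection

THREE_PITS = [(-35, -55, 12, 4), (35, -20, 12, 4), (0, 60, 12, 4)]


def test_detect_three_pits():
    pts = pitted_grid(spacing=2.0, pits=THREE_PITS)
    model = plane_model(pts)
    tpi = compute_tpi(model, radius=20.0)
    regions = detect_pit_regions(tpi, model, threshold=1.0)
    assert len(regions) == 3
    got = sorted((round(r.centroid_xy[0]), round(r.centroid_xy[1]))
                 for r in regions)
    want = sorted((p[0], p[1]) for p in THREE_PITS)
    for (gx, gy), (wx, wy) in zip(got, want):
        assert abs(gx - wx) <= 2 and abs(gy - wy) <= 2
    assert [r.pit_id for r in regions] == ["T-P01", "T-P02", "T-P03"]


def test_detect_flat_surface_finds_nothing():
    model = plane_model(grid_points(40, 60, 2.0))
    tpi = compute_tpi(model, radius=20.0)
    assert detect_pit_regions(tpi, model) == []


def test_detect_small_dimple_filtered():
    """A 7 mm-long depression fails the 10 mm discrete-pit criterion."""
    pits = [(0, 0, 3.5, 2.0)]                  # bbox ~7 mm
    pts = pitted_grid(spacing=1.0, x_half=30, y_half=30, pits=pits)
    model = plane_model(pts)
    tpi = compute_tpi(model, radius=15.0)
    assert detect_pit_regions(tpi, model, threshold=0.3) == []
    kept = detect_pit_regions(tpi, model, threshold=0.3, min_length=5.0)
    assert len(kept) == 1


def test_detect_regions_disjoint_and_maximal():
    pts = pitted_grid(spacing=2.0, pits=THREE_PITS, noise_sd=0.05, seed=3)
    model = plane_model(pts)
    tpi = compute_tpi(model, radius=20.0)
    threshold, linkage = 1.0, 8.0
    regions = detect_pit_regions(tpi, model, threshold=threshold,
                                 linkage_radius=linkage)
    members = [set(r.member_indices.tolist()) for r in regions]
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            assert not (members[i] & members[j])
    # maximality: every masked point within the linkage radius of a region
    # belongs to that region
    mask_idx = tpi.point_index[tpi.defined & (tpi.values < -threshold)]
    mask_xy = model.points[mask_idx][:, :2]
    for r, mem in zip(regions, members):
        d = np.linalg.norm(
            mask_xy[:, None, :]
            - model.points[r.member_indices][None, :, :2], axis=2)
        close = mask_idx[(d <= linkage).any(axis=1)]
        assert set(close.tolist()) <= mem


def test_detect_wrong_model_pairing():
    m1 = plane_model(grid_points(20, 20, 2.0), tool_id="A")
    m2 = plane_model(grid_points(20, 20, 2.0), tool_id="B")
    tpi = compute_tpi(m1, radius=10.0)
    with pytest.raises(PairingError):
        detect_pit_regions(tpi, m2)


def test_default_threshold_floor_and_mad():
    flat = compute_tpi(plane_model(grid_points(30, 30, 2.0)), radius=10.0)
    assert default_depression_threshold(flat) == pytest.approx(0.3)
    noisy_pts = grid_points(30, 30, 2.0)
    noisy_pts[:, 2] += np.random.default_rng(4).normal(0, 2.0, len(noisy_pts))
    noisy = compute_tpi(plane_model(noisy_pts), radius=10.0)
    v = noisy.values[noisy.defined]
    mad = np.median(np.abs(v - np.median(v)))
    assert default_depression_threshold(noisy) == pytest.approx(3 * mad)
    assert default_depression_threshold(noisy) > 0.3


# ----------------------------------------------------------------- depth

def detected_cap_region(radius=15.0, depth=5.0, spacing=1.0, noise=0.0,
                        seed=0):
    pts = pitted_grid(spacing=spacing, x_half=50, y_half=50,
                      pits=[(0, 0, radius, depth)], noise_sd=noise, seed=seed)
    model = box_model(pts, 50, 50, 40.0)
    tpi = compute_tpi(model, radius=20.0)
    regions = detect_pit_regions(tpi, model, threshold=0.3)
    assert len(regions) == 1
    return model, regions[0]


def test_depth_spherical_cap_exact():
    model, region = detected_cap_region()
    hull = compute_convex_hull(model)
    measure_pit_depth(region, hull, model)
    # deepest member sits at the cap bottom, 5 mm below the hull top facet
    assert region.depth_max_mm == pytest.approx(-5.0, abs=0.02)
    assert -5.0 <= region.depth_mm < -0.3
    assert region.depth_mm > region.depth_max_mm


def test_depth_matches_mesh_distance_oracle():
    """|hull deviation| equals point-to-hull-mesh distance from an
    independent implementation (trimesh, brute force over facets)."""
    import trimesh
    model, region = detected_cap_region(spacing=2.0)
    hull = compute_convex_hull(model)
    measure_pit_depth(region, hull, model)
    mesh = trimesh.Trimesh(vertices=model.points, faces=hull.hull_facets,
                           process=False)
    members = model.points[region.member_indices]
    _, dist, _ = trimesh.proximity.closest_point_naive(mesh, members)
    d = region.extras["member_hull_distances"]
    assert np.all(d <= 1e-9)
    np.testing.assert_allclose(-d, dist, atol=1e-8)


def test_depth_monotone_in_true_depth():
    prev = 0.0
    for depth in (2.0, 4.0, 6.0, 8.0):
        pts = pitted_grid(spacing=1.5, x_half=40, y_half=40,
                          pits=[(0, 0, 14, depth)])
        model = box_model(pts, 40, 40, 40.0)
        tpi = compute_tpi(model, radius=20.0)
        regions = detect_pit_regions(tpi, model, threshold=0.3)
        assert len(regions) == 1
        hull = compute_convex_hull(model)
        measure_pit_depth(regions[0], hull, model)
        assert regions[0].depth_max_mm < prev
        prev = regions[0].depth_max_mm


def test_depth_pairing_error():
    model, region = detected_cap_region(spacing=2.0)
    other = plane_model(grid_points(20, 20, 2.0), tool_id="OTHER")
    hull = compute_convex_hull(model)
    with pytest.raises(PairingError):
        measure_pit_depth(region, hull, other)


# -------------------------------------------------------------- gradient

def test_gradient_flat_is_zero():
    flat = plane_model(grid_points(30, 30, 1.0))
    ramp_region = detect_ramp_region(flat, slope=0.0)
    measure_pit_gradient(ramp_region, flat, fit_radius=2.5)
    assert ramp_region.gradient == pytest.approx(0.0, abs=1e-12)


def detect_ramp_region(model, slope):
    """Fake region spanning the interior of a plane model (for slope tests)."""
    from percwear.pit_morphometry import PitRegion
    pts = model.points
    interior = (np.abs(pts[:, 0]) < 20) & (np.abs(pts[:, 1]) < 20)
    idx = np.where(interior)[0]
    return PitRegion(tool_id=model.tool_id, pit_id="T-P01", plane="A",
                     member_indices=idx, centroid_xy=(0.0, 0.0))


def test_gradient_ramp_exact():
    """Plane z = 0.25 y has gradient exactly 0.25 (rise over run)."""
    pts = grid_points(30, 30, 1.0)
    pts[:, 2] = 0.25 * pts[:, 1]
    model = plane_model(pts)
    region = detect_ramp_region(model, 0.25)
    measure_pit_gradient(region, model, fit_radius=2.5)
    assert region.gradient == pytest.approx(0.25, abs=1e-10)


def test_gradient_oblique_plane_exact():
    """z = 0.3x - 0.4y has slope hypot(0.3, 0.4) = 0.5."""
    pts = grid_points(30, 30, 1.0)
    pts[:, 2] = 0.3 * pts[:, 0] - 0.4 * pts[:, 1]
    model = plane_model(pts)
    region = detect_ramp_region(model, 0.5)
    measure_pit_gradient(region, model, fit_radius=2.5)
    assert region.gradient == pytest.approx(0.5, abs=1e-10)


def test_gradient_spherical_cap_quadrature_oracle():
    """Mean slope over the inner cap equals the area-weighted integral of
    the analytic slope r / sqrt(R^2 - r^2)."""
    radius, depth = 15.0, 5.0
    R = (radius**2 + depth**2) / (2 * depth)
    fit_radius = 1.0
    pts = pitted_grid(spacing=0.4, x_half=25, y_half=25,
                      pits=[(0, 0, radius, depth)])
    model = plane_model(pts)
    from percwear.pit_morphometry import PitRegion
    r = np.hypot(pts[:, 0], pts[:, 1])
    inner = radius - fit_radius          # keep fit windows inside the cap
    idx = np.where(r <= inner)[0]
    region = PitRegion(tool_id="T", pit_id="T-P01", plane="A",
                       member_indices=idx, centroid_xy=(0.0, 0.0))
    measure_pit_gradient(region, model, fit_radius=fit_radius)
    integrand = lambda rr: (rr / np.sqrt(R * R - rr * rr)) * 2 * np.pi * rr
    oracle = quad(integrand, 0, inner)[0] / (np.pi * inner**2)
    assert region.gradient == pytest.approx(oracle, rel=0.02)


def test_gradient_ignores_other_faces():
    """On a full block surface, the bottom face shares the pit's planimetric
    footprint; local slope fits must use only the active plane's points."""
    from percwear.synthetic import PitSpec, SyntheticSurfaceSpec, generate_surface
    spec = SyntheticSurfaceSpec(tool_id="T", length_mm=160, width_mm=120,
                                thickness_mm=40, grain_noise_sd=0.05,
                                density_per_cm2=50.0, seed=9,
                                pits=[PitSpec(0, 0, 15, 5)])
    model, _ = generate_surface(spec)
    tpi = compute_tpi(model)
    regions = detect_pit_regions(tpi, model)
    assert len(regions) == 1
    measure_pit_gradient(regions[0], model, fit_radius=3.5)
    # analytic slope of the cap never exceeds a/ (R - d) ~ 0.75 at the rim
    assert 0.1 < regions[0].gradient < 0.8


# ------------------------------------------------------------- roughness

def test_roughness_plane_is_zero():
    pts = grid_points(10, 10, 0.25)
    pts[:, 2] = 0.1 * pts[:, 0] + 0.05 * pts[:, 1]   # any plane, not just z=0
    model = plane_model(pts)
    region = detect_ramp_region(model, 0.0)
    region.member_indices = np.arange(len(pts))
    measure_pit_roughness(region, model, window=0.6)
    assert region.roughness_mm == pytest.approx(0.0, abs=1e-12)


def test_roughness_bounded_by_noise_and_matches_oracle():
    """Noisy plane: roughness is positive, below the noise amplitude, and
    equals an independently coded neighbourhood-plane oracle."""
    rng = np.random.default_rng(5)
    pts = grid_points(8, 8, 0.25)
    pts[:, 2] += rng.uniform(-0.2, 0.2, len(pts))
    model = plane_model(pts)
    region = detect_ramp_region(model, 0.0)
    region.member_indices = np.arange(len(pts))
    window = 0.6
    measure_pit_roughness(region, model, window=window)
    assert 0.0 < region.roughness_mm < 0.2

    # oracle: brute-force neighbour search + orthogonal plane via eigh
    vals = []
    for m in range(len(pts)):
        d = np.linalg.norm(pts - pts[m], axis=1)
        nb = pts[d <= window]
        if len(nb) < 4:
            continue
        c = nb.mean(axis=0)
        cov = (nb - c).T @ (nb - c)
        w, v = np.linalg.eigh(cov)
        normal = v[:, 0]
        vals.append(abs(float((pts[m] - c) @ normal)))
    assert region.roughness_mm == pytest.approx(np.mean(vals), abs=1e-9)


def test_roughness_smooth_sinusoid_small():
    """Wavelength 50 mm, amplitude 2 mm: locally planar at a 0.5 mm window."""
    pts = grid_points(15, 15, 0.2)
    pts[:, 2] = 2.0 * np.sin(2 * np.pi * pts[:, 1] / 50.0)
    model = plane_model(pts)
    region = detect_ramp_region(model, 0.0)
    region.member_indices = np.arange(len(pts))
    measure_pit_roughness(region, model, window=0.5)
    assert region.roughness_mm < 0.05


def test_roughness_insufficient_support():
    from percwear.errors import InsufficientSupportError
    pts = grid_points(20, 20, 5.0)
    model = plane_model(pts)
    region = detect_ramp_region(model, 0.0)
    with pytest.raises(InsufficientSupportError):
        measure_pit_roughness(region, model, window=0.5)  # << spacing
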