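import numpy as np
import pytest
import shapely
import shapely.geometry as sg
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull

from curvhdr import geometry as G
from curvhdr.density import GridSpec
from curvhdr.errors import (
    DegenerateGeometryError,
    FormatError,
    ValidationError,
)

SQRT2PI = np.sqrt(2 * np.pi)


def unit_square():
    return G.Polygon(np.array([[0, 0], [0, 1], [1, 1], [1, 0], [0, 0]], float))


def unit_cube():
    import trimesh

    box = trimesh.creation.box(extents=(1, 1, 1))
    box.apply_translation([0.5, 0.5, 0.5])
    return G.TriMesh(box.vertices, box.faces)


def random_convex_polygon(rng, n=9, scale=1.0):
    pts = rng.normal(scale=scale, size=(n + 6, 2))
    hull = ConvexHull(pts)
    ring = pts[hull.vertices]
    return G.Polygon(np.vstack([ring, ring[0]]))


def random_convex_mesh(rng, n=50, scale=1.0):
    return G.convex_hull(rng.normal(scale=scale, size=(n, 3)))


class TestMeasures:
    def test_polygon_area_exact(self):
        assert G.polygon_area(unit_square()) == pytest.approx(1.0)
        tri = G.Polygon(np.array([[0, 0], [1, 0], [0, 1], [0, 0]], float))
        assert G.polygon_area(tri) == pytest.approx(0.5)

    def test_polygon_area_monte_carlo(self, rng):
        poly = random_convex_polygon(rng)
        lo = poly.vertices.min(axis=0)
        hi = poly.vertices.max(axis=0)
        m = 10**6
        draws = rng.uniform(lo, hi, size=(m, 2))
        hit = G.points_in_polygon(draws, poly).mean()
        box_area = np.prod(hi - lo)
        mc_err = np.sqrt(hit * (1 - hit) / m) * box_area
        assert G.polygon_area(poly) == pytest.approx(hit * box_area, abs=3 * mc_err)

    def test_mesh_volume_exact(self):
        assert G.trimesh_volume(unit_cube()) == pytest.approx(1.0)
        tet = G.convex_hull(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        )
        assert G.trimesh_volume(tet) == pytest.approx(1 / 6)

    def test_mesh_volume_monte_carlo(self, rng):
        mesh = random_convex_mesh(rng)
        lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
        m = 4 * 10**5
        draws = rng.uniform(lo, hi, size=(m, 3))
        hit = G.points_in_polyhedron(draws, mesh).mean()
        box_vol = np.prod(hi - lo)
        mc_err = np.sqrt(hit * (1 - hit) / m) * box_vol
        assert G.trimesh_volume(mesh) == pytest.approx(hit * box_vol, abs=3 * mc_err)

    def test_degenerate_ring_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            G.Polygon(np.array([[0, 0], [1, 1], [2, 2], [0, 0]], float))


class TestConvexHull:
    def test_square_recovered(self, rng):
        corners = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], float)
        interior = rng.uniform(0.1, 0.9, size=(40, 2))
        hull = G.convex_hull(np.vstack([corners, interior]))
        assert G.polygon_area(hull) == pytest.approx(1.0)
        assert len(hull.vertices) == 5  # 4 corners + closure

    def test_idempotent(self, rng):
        hull = G.convex_hull(rng.normal(size=(30, 2)))
        again = G.convex_hull(hull)
        assert G.polygon_area(again) == pytest.approx(G.polygon_area(hull), rel=1e-12)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_contains_every_input_point(self, d, rng):
        pts = rng.normal(size=(60, d))
        hull = G.convex_hull(pts)
        assert G.component_contains(hull, pts).all()

    def test_degenerate_input(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(DegenerateGeometryError):
            G.convex_hull(line)


class TestGrowRegion:
    def test_interval_symmetric_widening(self):
        grown = G.grow_region(G.Interval(0, 1), 2.0)
        assert (grown.lo, grown.hi) == (-0.5, 1.5)

    def test_square_area_ratio(self):
        grown = G.grow_region(unit_square(), 4.0)
        assert G.polygon_area(grown) == pytest.approx(4.0, rel=0.005)

    def test_icosahedron_volume_ratio_and_containment(self):
        import trimesh

        ico = trimesh.creation.icosahedron()
        mesh = G.TriMesh(ico.vertices, ico.faces)
        grown = G.grow_region(mesh, 8.0)
        assert G.trimesh_volume(grown) / G.trimesh_volume(mesh) == pytest.approx(
            8.0, rel=0.005
        )
        assert G.points_in_polyhedron(mesh.vertices, grown).all()

    def test_rejects_small_growth_factor(self):
        with pytest.raises(ValidationError):
            G.grow_region(G.Interval(0, 1), 1.0)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([2.0, 4.0]))
    def test_grown_polygon_contains_input(self, seed, factor):
        r = np.random.default_rng(seed)
        poly = random_convex_polygon(r)
        grown = G.grow_region(poly, factor)
        assert G.points_in_polygon(poly.vertices, grown).all()


class TestContainment:
    def test_polygon_trivial_points(self, rng):
        poly = random_convex_polygon(rng)
        centroid = poly.vertices[:-1].mean(axis=0)
        far = poly.vertices.max(axis=0) + 10.0
        res = G.points_in_polygon(np.vstack([centroid, far]), poly)
        assert res.tolist() == [True, False]

    def test_polygon_vs_winding_number_oracle(self, rng):
        for _ in range(10):
            poly = random_convex_polygon(rng, n=rng.integers(5, 12))
            pts = rng.uniform(-3, 3, size=(10**4, 2))
            mine = G.points_in_polygon(pts, poly)
            poly_s = poly.to_shapely()
            shapely.prepare(poly_s)
            oracle = shapely.contains_xy(poly_s, pts[:, 0], pts[:, 1])
            # boundary-free sample: even-odd and winding agree exactly
            assert np.array_equal(mine, oracle)

    def test_polygon_boundary_counts_inside(self):
        sq = unit_square()
        edge_pts = np.array([[0.5, 0.0], [0.0, 0.25], [1.0, 1.0]])
        assert G.points_in_polygon(edge_pts, sq).all()

    def test_polyhedron_trivial_points(self):
        cube = unit_cube()
        res = G.points_in_polyhedron(np.array([[0.5, 0.5, 0.5], [2, 2, 2]]), cube)
        assert res.tolist() == [True, False]

    def test_polyhedron_vs_halfspace_oracle(self, rng):
        for _ in range(10):
            mesh = random_convex_mesh(rng, n=30)
            hull = ConvexHull(mesh.vertices)
            pts = rng.uniform(-2, 2, size=(10**4, 3))
            mine = G.points_in_polyhedron(pts, mesh, seed=1)
            oracle = np.all(
                pts @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-9, axis=1
            )
            assert np.array_equal(mine, oracle)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_translation_invariance(self, seed):
        r = np.random.default_rng(seed)
        poly = random_convex_polygon(r)
        pts = r.uniform(-2, 2, size=(500, 2))
        shift = r.normal(size=2) * 10
        shifted = G.Polygon(poly.vertices + shift)
        assert np.array_equal(
            G.points_in_polygon(pts, poly), G.points_in_polygon(pts + shift, shifted)
        )
        assert G.polygon_area(shifted) == pytest.approx(G.polygon_area(poly), rel=1e-9)


class TestIndicatorToRegions:
    def test_run_of_true_nodes(self):
        grid = GridSpec([0.0], [10.0], (11,))
        flags = np.zeros(11, bool)
        flags[2:7] = True
        regions = G.indicator_to_regions(flags, grid, 1)
        assert len(regions) == 1
        assert (regions[0].lo, regions[0].hi) == (2.0, 6.0)

    def test_disk_area_recovered(self):
        grid = GridSpec([-1, -1], [1, 1], (101, 101))
        nodes = grid.node_coords().reshape(101, 101, 2)
        flags = (nodes**2).sum(-1) <= 0.5**2
        regions = G.indicator_to_regions(flags, grid, 2)
        assert len(regions) == 1
        assert G.polygon_area(regions[0]) == pytest.approx(np.pi * 0.25, rel=0.05)

    def test_two_blobs_two_components(self):
        grid = GridSpec([-2, -2], [2, 2], (81, 81))
        nodes = grid.node_coords().reshape(81, 81, 2)
        flags = ((nodes - [-1, 0]) ** 2).sum(-1) <= 0.3**2
        flags |= ((nodes - [1, 0]) ** 2).sum(-1) <= 0.3**2
        assert len(G.indicator_to_regions(flags, grid, 2)) == 2

    def test_all_false_gives_empty_list(self):
        grid = GridSpec([0.0], [1.0], (11,))
        assert G.indicator_to_regions(np.zeros(11, bool), grid, 1) == []

    def test_flagged_nodes_lie_inside_components(self, rng):
        grid = GridSpec([-2, -2], [2, 2], (81, 81))
        nodes = grid.node_coords().reshape(81, 81, 2)
        flags = ((nodes - [0.3, -0.2]) ** 2).sum(-1) <= 0.7**2
        regions = G.indicator_to_regions(flags, grid, 2)
        flagged_xy = nodes[flags]
        inside = np.zeros(len(flagged_xy), bool)
        for reg in regions:
            # one-cell tolerance: nudge the polygon outward via its hull
            inside |= G.points_in_polygon(flagged_xy, reg)
        frac_near = inside.mean()
        assert frac_near > 0.95  # boundary nodes sit on the 0.5-contour


class TestDensityLevelRegions:
    def test_normal_hpd_interval(self):
        grid = GridSpec([-5.0], [5.0], (201,))
        x = grid.axes()[0]
        fhat = np.exp(-0.5 * x * x) / SQRT2PI
        level = float(np.exp(-0.5 * 1.6449**2) / SQRT2PI)
        regions = G.density_level_regions(fhat, level, grid, 1)
        assert len(regions) == 1
        assert regions[0].lo == pytest.approx(-1.6449, abs=grid.spacing[0])
        assert regions[0].hi == pytest.approx(1.6449, abs=grid.spacing[0])

    def test_level_above_max_empty(self):
        grid = GridSpec([-5.0], [5.0], (101,))
        fhat = np.exp(-0.5 * grid.axes()[0] ** 2) / SQRT2PI
        assert G.density_level_regions(fhat, 1.0, grid, 1) == []

    def test_level_just_below_max(self):
        grid = GridSpec([-5, -5], [5, 5], (101, 101))
        nodes = grid.node_coords().reshape(101, 101, 2)
        fhat = np.exp(-0.5 * (nodes**2).sum(-1)) / (2 * np.pi)
        regions = G.density_level_regions(fhat, 0.999 * fhat.max(), grid, 2)
        assert len(regions) == 1
        assert G.polygon_area(regions[0]) < 0.05

    def test_bimodal_above_saddle_two_components(self):
        grid = GridSpec([-6.0], [6.0], (301,))
        x = grid.axes()[0]
        fhat = 0.5 * (
            np.exp(-0.5 * (x - 2.5) ** 2) + np.exp(-0.5 * (x + 2.5) ** 2)
        ) / SQRT2PI
        saddle = fhat[150]  # symmetric: the midpoint is the saddle
        regions = G.density_level_regions(fhat, 1.5 * saddle, grid, 1)
        assert len(regions) == 2

    def test_sphere_volume_recovered(self):
        grid = GridSpec([-2, -2, -2], [2, 2, 2], (61, 61, 61))
        nodes = grid.node_coords().reshape(61, 61, 61, 3)
        fhat = np.exp(-0.5 * (nodes**2).sum(-1))
        level = float(np.exp(-0.5 * 1.0))  # radius-1 sphere
        regions = G.density_level_regions(fhat, level, grid, 3)
        assert len(regions) == 1
        assert G.trimesh_volume(regions[0]) == pytest.approx(4 * np.pi / 3, rel=0.05)


class TestSerialization:
    def test_polygon_round_trip(self, rng):
        region = G.GateRegion(2, [random_convex_polygon(rng)], space_tag="original")
        back = G.region_from_dict(G.region_to_dict(region))
        assert np.allclose(
            back.components[0].vertices, region.components[0].vertices, atol=1e-12
        )
        assert back.space_tag == "original"

    def test_trimesh_round_trip(self, rng):
        region = G.GateRegion(3, [random_convex_mesh(rng)])
        back = G.region_from_dict(G.region_to_dict(region))
        assert np.allclose(back.components[0].vertices, region.components[0].vertices)
        assert np.array_equal(back.components[0].faces, region.components[0].faces)

    def test_unknown_schema_version(self):
        with pytest.raises(FormatError):
            G.region_from_dict({"schema_version": 99, "dimension": 1, "components": []})
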