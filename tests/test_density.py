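import numpy as np
import pytest

from curvhdr import density as D
from curvhdr.errors import ValidationError

SQRT2PI = np.sqrt(2 * np.pi)


def _direct_kde(points, axis_nodes, h):
    """O(n * grid) direct-sum Gaussian KDE oracle, d=1."""
    u = (axis_nodes[:, None] - points[None, :]) / h
    return np.exp(-0.5 * u * u).mean(axis=1) / (SQRT2PI * h)


class TestCurvatureBandwidth:
    @pytest.mark.parametrize(
        "d,n,expected",
        [(1, 1000, 0.43618), (2, 10000, 0.37145)],  # frozen from (4/((d+6)n))^(1/(d+8))
    )
    def test_table_formula(self, d, n, expected):
        assert D.default_curvature_bandwidth(d, n) == pytest.approx(expected, abs=5e-5)

    def test_monotone_in_n(self):
        vals = [D.default_curvature_bandwidth(2, n) for n in (100, 1000, 10000)]
        assert vals[0] > vals[1] > vals[2]

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            D.default_curvature_bandwidth(4, 100)
        with pytest.raises(ValidationError):
            D.default_curvature_bandwidth(2, 1)


class TestLinearBinning:
    def test_point_on_node_and_midway(self):
        grid = D.GridSpec([0.0], [10.0], (11,))
        c = D.linear_bin(np.array([[3.0]]), grid)
        assert c[3] == pytest.approx(1.0) and c.sum() == pytest.approx(1.0)
        c = D.linear_bin(np.array([[3.5]]), grid)
        assert c[3] == pytest.approx(0.5) and c[4] == pytest.approx(0.5)

    def test_mass_conservation(self, rng):
        pts = rng.uniform(-1, 1, size=(500, 2))
        grid = D.GridSpec([-2, -2], [2, 2], (33, 33))
        c = D.linear_bin(pts, grid)
        assert c.sum() == pytest.approx(500.0, abs=1e-9)

    def test_out_of_bounds_points_lose_mass(self):
        grid = D.GridSpec([0.0], [1.0], (11,))
        c = D.linear_bin(np.array([[0.5], [5.0]]), grid)
        assert c.sum() == pytest.approx(1.0)


class TestKDEOnGrid:
    def test_single_kernel_peak(self):
        for d in (1, 2):
            grid = D.GridSpec([-4.0] * d, [4.0] * d, (65,) * d)
            f = D.kde_on_grid(D.linear_bin(np.zeros((1, d)), grid), grid, 1.0)
            center = (32,) * d
            assert f[center] == pytest.approx((2 * np.pi) ** (-d / 2), rel=1e-9)

    def test_integrates_to_one(self, rng):
        x = rng.standard_normal((10000, 1))
        h = D.default_curvature_bandwidth(1, 10000)
        grid = D.GridSpec.from_points(x, 3.7 * h, 151)
        f = D.kde_on_grid(D.linear_bin(x, grid), grid, h)
        assert 0.98 <= np.trapezoid(f, dx=grid.spacing[0]) <= 1.02

    def test_matches_direct_sum(self, rng):
        # points spread over the grid; binning error is O(spacing^2)
        x = rng.uniform(-2, 2, size=(200, 1))
        h = 0.5
        grid = D.GridSpec([-3.0], [3.0], (97,))  # spacing = h / 8
        f = D.kde_on_grid(D.linear_bin(x, grid), grid, h)
        direct = _direct_kde(x[:, 0], grid.axes()[0], h)
        nodes = grid.axes()[0]
        in_support = (nodes >= x.min()) & (nodes <= x.max())
        rel = np.abs(f - direct)[in_support] / direct[in_support]
        assert rel.max() < 1e-3
        assert np.abs(f - direct).max() / direct.max() < 2e-3

    def test_rejects_bad_bandwidth(self):
        grid = D.GridSpec([0.0], [1.0], (11,))
        with pytest.raises(ValidationError):
            D.kde_on_grid(np.zeros(11), grid, -1.0)


class TestHessianOnGrid:
    def test_single_point_second_derivative(self):
        grid = D.GridSpec([-4.0], [4.0], (65,))
        hess = D.hessian_on_grid(D.linear_bin(np.zeros((1, 1)), grid), grid, 1.0)
        assert hess[32, 0] == pytest.approx(-1 / SQRT2PI, rel=1e-9)

    def test_matches_direct_sum(self, rng):
        # binning error of the 2nd-derivative kernel is O(spacing^2)
        x = rng.uniform(-2, 2, size=(150, 1))
        h = 0.5
        grid = D.GridSpec([-3.0], [3.0], (193,))  # spacing = h / 16
        hess = D.hessian_on_grid(D.linear_bin(x, grid), grid, h)
        u = (grid.axes()[0][:, None] - x[None, :, 0]) / h
        direct = ((u * u - 1) * np.exp(-0.5 * u * u) / SQRT2PI).mean(axis=1) / h**3
        assert np.abs(hess[:, 0] - direct).max() / np.abs(direct).max() < 1e-3

    def test_bivariate_normal_hessian_at_mode(self, rng):
        x = rng.standard_normal((40000, 2))
        h = 0.25
        grid = D.GridSpec([-4, -4], [4, 4], (129, 129))
        hess = D.hessian_on_grid(D.linear_bin(x, grid), grid, h)
        center = (64, 64)
        # smoothing shrinks the mode curvature toward the population value
        # of N(0, (1+h^2) I); 25% absorbs that bias plus sampling noise
        target = -1 / (2 * np.pi)
        assert hess[center][0] == pytest.approx(target, rel=0.25)
        assert hess[center][2] == pytest.approx(target, rel=0.25)
        assert abs(hess[center][1]) < 0.25 * abs(target)


class TestGaussianRFunctional:
    def test_d1_closed_form(self):
        # int phi''(u)^2 du = 3 / (8 sqrt(pi))
        assert D.gaussian_hessian_rfunctional(1)[0, 0] == pytest.approx(
            3 / (8 * np.sqrt(np.pi)), rel=1e-12
        )

    @pytest.mark.parametrize("d", [2, 3])
    def test_matches_numerical_quadrature(self, d):
        # brute-force quadrature oracle over a truncated lattice
        grid1 = np.linspace(-6, 6, 121)
        du = grid1[1] - grid1[0]
        mesh = np.meshgrid(*([grid1] * d), indexing="ij")
        u = np.stack([m.ravel() for m in mesh], axis=1)
        phi = np.exp(-0.5 * (u**2).sum(1)) / (2 * np.pi) ** (d / 2)
        pairs = D.vech_pairs(d)
        derivs = []
        for a, b in pairs:
            if a == b:
                derivs.append((u[:, a] ** 2 - 1) * phi)
            else:
                derivs.append(u[:, a] * u[:, b] * phi)
        R_num = np.array(
            [[(da * db).sum() * du**d for db in derivs] for da in derivs]
        )
        assert np.allclose(D.gaussian_hessian_rfunctional(d), R_num, atol=1e-6)


class TestSignificantCurvature:
    def test_interior_type_one_error_controlled(self, rng):
        # the smoothed uniform is flat (null true) away from the support
        # boundary; pointwise rejections there should not exceed alpha
        fracs = []
        h = D.default_curvature_bandwidth(2, 5000)
        for _ in range(10):
            x = rng.uniform(0, 1, size=(5000, 2))
            x = (x - x.mean(0)) / x.std(0, ddof=1)
            grid = D.GridSpec.from_points(x, 3.7 * h, 151)
            field = D.estimate_density_field(x, grid, h)
            flags = D.significant_negative_curvature(
                field, 5000, D.CurvatureTestConfig(adjustment="pointwise")
            )
            nodes = grid.node_coords().reshape(*grid.shape, 2)
            interior = np.all(
                (nodes > x.min(0) + 3 * h) & (nodes < x.max(0) - 3 * h), axis=-1
            )
            fracs.append(flags[interior].mean())
        assert np.mean(fracs) <= 0.05

    def test_normal_mode_is_flagged(self, rng):
        x = rng.standard_normal((10000, 2))
        h = D.default_curvature_bandwidth(2, 10000)
        grid = D.GridSpec.from_points(x, 3.7 * h, 151)
        field = D.estimate_density_field(x, grid, h)
        flags = D.significant_negative_curvature(field, 10000)
        assert flags.any()
        nearest = tuple(
            int(np.argmin(np.abs(ax))) for ax in grid.axes()
        )  # node nearest the origin
        assert flags[nearest]

    def test_saddle_between_modes_not_flagged(self, rng):
        x = np.concatenate(
            [rng.normal(-3, 1, (8000, 1)), rng.normal(3, 1, (8000, 1))], axis=0
        )
        h = D.default_curvature_bandwidth(1, len(x))
        grid = D.GridSpec.from_points(x, 3.7 * h, 151)
        field = D.estimate_density_field(x, grid, h)
        flags = D.significant_negative_curvature(field, len(x))
        saddle = int(np.argmin(np.abs(grid.axes()[0])))
        # f'' > 0 at the saddle between well-separated equal modes
        assert not flags[saddle]

    def test_flags_invariant_under_event_permutation(self, rng):
        x = rng.standard_normal((2000, 2))
        h = D.default_curvature_bandwidth(2, 2000)
        grid = D.GridSpec.from_points(x, 3.7 * h, 101)
        f1 = D.estimate_density_field(x, grid, h)
        f2 = D.estimate_density_field(x[rng.permutation(2000)], grid, h)
        a = D.significant_negative_curvature(f1, 2000)
        b = D.significant_negative_curvature(f2, 2000)
        assert np.array_equal(a, b)
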