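import numpy as np
import pytest

from geogain import (
    GridSpec,
    NeighborhoodConfig,
    VariogramModel,
    krige_grid,
    krige_point,
    ok_weights,
)
from geogain.errors import DegenerateGeometryError


def oracle_ok(coords, values, vm_params, target):
    """Independent dense ordinary-kriging solve with its own gamma code.

    Spherical model only; written from the textbook system, sharing no code
    with the package implementation.
    """
    c0, c, a = vm_params

    def gamma(h):
        h = np.asarray(h, dtype=float)
        hr = np.minimum(h / a, 1.0)
        g = c0 + c * (1.5 * hr - 0.5 * hr**3)
        return np.where(h == 0, 0.0, g)

    n = len(coords)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            A[i, j] = gamma(np.hypot(*(coords[i] - coords[j])))
        A[i, n] = 1.0
        A[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        b[i] = gamma(np.hypot(*(coords[i] - target)))
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    w = sol[:n]
    return float(w @ values), float(w @ b[:n] + sol[n])


class TestKrigePoint:
    def test_constant_data_forces_constant_estimate(self, spherical_vm):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 50, (12, 2))
        values = np.full(12, 7.0)
        for target in [(0, 0), (25, 25), (200, -50)]:
            est, var = krige_point(coords, values, spherical_vm, target)
            assert est == pytest.approx(7.0, abs=1e-9)

    def test_exact_interpolation_with_zero_nugget(self, spherical_vm):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 50, (15, 2))
        values = rng.normal(10, 2, 15)
        for i in (0, 7, 14):
            est, _ = krige_point(coords, values, spherical_vm, coords[i])
            assert est == pytest.approx(values[i], abs=1e-8)

    def test_three_point_configuration_matches_oracle(self, three_point_config):
        coords, values = three_point_config
        vm = VariogramModel("spherical", nugget=0.0, partial_sill=1.0,
                            range_=50.0)
        est, var = krige_point(coords, values, vm, (5.0, 5.0))
        ref_est, ref_var = oracle_ok(coords, values, (0.0, 1.0, 50.0), (5.0, 5.0))
        assert est == pytest.approx(ref_est, abs=1e-10)
        assert var == pytest.approx(ref_var, abs=1e-10)

    def test_weights_sum_to_one(self, spherical_vm):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 100, (30, 2))
        for target in [(0, 0), (50, 50), (99, 1)]:
            w, _ = ok_weights(coords, spherical_vm, target)
            assert w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_kriging_variance_nonnegative(self, spherical_vm):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 100, (25, 2))
        values = rng.normal(0, 1, 25)
        for target in [(10, 10), (50, 80), (150, 150)]:
            _, var = krige_point(coords, values, spherical_vm, target)
            assert var >= -1e-10

    def test_no_neighbor_in_range_is_masked_not_error(self, spherical_vm):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        values = np.array([1.0, 2.0])
        nb = NeighborhoodConfig(mode="local", max_search_distance=5.0)
        est, var = krige_point(coords, values, spherical_vm, (100.0, 100.0), nb)
        assert np.isnan(est) and np.isnan(var)

    def test_degenerate_geometry_rejected(self, spherical_vm):
        with pytest.raises(DegenerateGeometryError):
            krige_point(np.zeros((4, 2)), np.arange(4.0), spherical_vm, (1, 1))

    def test_translation_invariance(self, spherical_vm):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 50, (20, 2))
        values = rng.normal(5, 1, 20)
        target = np.array([20.0, 30.0])
        shift = np.array([1234.5, -987.25])
        e1, _ = krige_point(coords, values, spherical_vm, target)
        e2, _ = krige_point(coords + shift, values, spherical_vm, target + shift)
        assert e2 == pytest.approx(e1, abs=1e-9)


class TestKrigeGrid:
    def test_single_cell_grid_reproduces_krige_point(self, three_point_config,
                                                     spherical_vm):
        coords, values = three_point_config
        spec = GridSpec(4.0, 4.0, 6.0, 6.0, 2.0)  # one cell centered at (5,5)
        g = krige_grid(coords, values, spherical_vm, spec)
        est, _ = krige_point(coords, values, spherical_vm, (5.0, 5.0))
        assert g.values[0, 0] == pytest.approx(est, abs=1e-12)

    def test_constant_training_gives_constant_grid(self, spherical_vm):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 40, (10, 2))
        spec = GridSpec(0, 0, 40, 40, 5.0)
        g = krige_grid(coords, np.full(10, 3.25), spherical_vm, spec)
        assert np.allclose(g.values, 3.25, atol=1e-9)
        assert not g.nodata_mask.any()

    def test_grid_matches_per_cell_oracle(self, three_point_config):
        coords, values = three_point_config
        vm = VariogramModel("spherical", nugget=0.0, partial_sill=1.0,
                            range_=50.0)
        spec = GridSpec(0.0, 0.0, 20.0, 20.0, 1.0)
        g = krige_grid(coords, values, vm, spec)
        xs, ys = spec.cell_centers()
        for i in range(0, 20, 3):
            for j in range(0, 20, 3):
                ref, _ = oracle_ok(coords, values, (0.0, 1.0, 50.0),
                                   (xs[i, j], ys[i, j]))
                assert g.values[i, j] == pytest.approx(ref, abs=1e-10)

    def test_local_equals_global_when_unconstrained(self, spherical_vm):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 30, (12, 2))
        values = rng.normal(0, 1, 12)
        spec = GridSpec(0, 0, 30, 30, 5.0)
        g_global = krige_grid(coords, values, spherical_vm, spec,
                              NeighborhoodConfig(mode="global",
                                                 max_neighbors=12,
                                                 min_neighbors=1))
        g_local = krige_grid(coords, values, spherical_vm, spec,
                             NeighborhoodConfig(mode="local",
                                                max_search_distance=1e6,
                                                max_neighbors=12,
                                                min_neighbors=1))
        assert np.array_equal(g_global.values, g_local.values)  # bitwise

    def test_neighbor_cap_path_matches_full_solve_far_field(self):
        """With max_neighbors < n, the capped solve still matches the oracle
        restricted to the same nearest points."""
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 100, (50, 2))
        values = rng.normal(0, 1, 50)
        vm = VariogramModel("spherical", nugget=0.05, partial_sill=1.0,
                            range_=60.0)
        nb = NeighborhoodConfig(max_neighbors=10, min_neighbors=1)
        target = np.array([33.0, 67.0])
        est, _ = krige_point(coords, values, vm, target, nb)
        d = np.hypot(coords[:, 0] - target[0], coords[:, 1] - target[1])
        sel = np.sort(np.argsort(d)[:10])
        ref, _ = oracle_ok(coords[sel], values[sel], (0.05, 1.0, 60.0), target)
        assert est == pytest.approx(ref, abs=1e-10)

    def test_grid_georeferencing(self, spherical_vm):
        coords = np.array([[0.0, 0.0], [10.0, 7.0], [3.0, 9.0]])
        spec = GridSpec(0.0, 0.0, 10.0, 7.0, 1.5)
        g = krige_grid(coords, np.array([1.0, 2.0, 3.0]), spherical_vm, spec,
                       crs=32632)
        # bounds padded up to whole pixels
        assert g.ncols == 7 and g.nrows == 5
        assert g.origin_y == pytest.approx(7.5)
        assert g.crs == 32632
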