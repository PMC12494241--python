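import math

import numpy as np
import pytest
from shapely.geometry import box

from geogain import (
    GridSpec,
    StudyArea,
    TrialDesign,
    VariogramModel,
    empirical_variogram,
    layout_treatments,
    make_trial,
    model_gamma,
    sample_harvest_tracks,
    simulate_gaussian_field,
)
from geogain.errors import ConfigurationError, SimulationError
from geogain.synthetic_fields import FieldTruth


def _design(n_strips, k, layout, strip=20.0):
    area = StudyArea(box(0, 0, n_strips * strip, 100.0), crs=32632)
    return TrialDesign(area=area, n_treatments=k, strip_width=strip,
                       layout=layout, orientation="columns")


class TestLayout:
    def test_interleaved_two_treatments(self):
        labels = [lb for lb, _ in layout_treatments(_design(6, 2, "interleaved"))]
        assert labels == ["T1", "T2", "T1", "T2", "T1", "T2"]

    def test_continuous_two_treatments(self):
        labels = [lb for lb, _ in layout_treatments(_design(6, 2, "continuous"))]
        assert labels == ["T1", "T1", "T1", "T2", "T2", "T2"]

    def test_interleaved_five_treatments(self):
        labels = [lb for lb, _ in layout_treatments(_design(10, 5, "interleaved"))]
        assert labels == ["T1", "T2", "T3", "T4", "T5"] * 2

    def test_continuous_beyond_two_rejected(self):
        with pytest.raises(ConfigurationError):
            _design(6, 3, "continuous")

    def test_strips_tile_the_area(self):
        design = _design(6, 2, "interleaved")
        strips = [g for _, g in layout_treatments(design)]
        total = sum(s.area for s in strips)
        assert total == pytest.approx(design.area.polygon.area)


class TestGaussianField:
    def test_zero_sill_rejected(self):
        vm = VariogramModel("spherical", nugget=0.0, partial_sill=0.0,
                            range_=10.0)
        with pytest.raises(SimulationError):
            simulate_gaussian_field(vm, GridSpec(0, 0, 20, 20, 2.0), 0.0, 1)

    def test_pure_nugget_iid_variance(self):
        vm = VariogramModel("spherical", nugget=1.0, partial_sill=0.0,
                            range_=10.0)
        g = simulate_gaussian_field(vm, GridSpec(0, 0, 100, 100, 2.0), 0.0,
                                    seed=6)
        v = g.values.ravel()
        assert np.var(v) == pytest.approx(1.0, rel=0.15)
        # spatial independence: lag-1 autocorrelation near zero
        r = np.corrcoef(g.values[:, :-1].ravel(), g.values[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_realizations_follow_the_model_variogram(self):
        """Empirical variogram of simulated fields tracks the model curve."""
        vm = VariogramModel("spherical", nugget=0.1, partial_sill=1.0,
                            range_=40.0)
        spec = GridSpec(0, 0, 120, 120, 2.0)
        gammas = []
        for seed in range(5):
            g = simulate_gaussian_field(vm, spec, 0.0, seed=seed)
            xs, ys = g.cell_centers()
            idx = np.random.default_rng(seed).choice(g.values.size, 700,
                                                     replace=False)
            coords = np.column_stack([xs.ravel()[idx], ys.ravel()[idx]])
            ev = empirical_variogram(coords, g.values.ravel()[idx],
                                     n_lags=10, max_dist=40.0)
            gammas.append(np.interp([10.0, 20.0, 30.0, 40.0],
                                    ev.lag_centers, ev.gamma_hat))
        mean_gamma = np.mean(gammas, axis=0)
        model = model_gamma(vm, np.array([10.0, 20.0, 30.0, 40.0]))
        assert np.allclose(mean_gamma, model, rtol=0.25)

    def test_seeded_reproducibility(self):
        vm = VariogramModel("exponential", nugget=0.1, partial_sill=1.0,
                            range_=30.0)
        spec = GridSpec(0, 0, 60, 60, 3.0)
        a = simulate_gaussian_field(vm, spec, 5.0, seed=9)
        b = simulate_gaussian_field(vm, spec, 5.0, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_linear_family_simulable_via_surrogate(self):
        vm = VariogramModel("linear", nugget=0.05, slope=0.01)
        g = simulate_gaussian_field(vm, GridSpec(0, 0, 60, 60, 3.0), 0.0, 2)
        assert np.isfinite(g.values).all()


class TestHarvestTracks:
    def _truth(self, design, noise_sd=0.0, effects=None):
        vm = VariogramModel("spherical", nugget=0.1, partial_sill=1.0,
                            range_=40.0)
        xmin, ymin, xmax, ymax = design.area.polygon.bounds
        spec = GridSpec(xmin, ymin, xmax, ymax, 4.0)
        baseline = simulate_gaussian_field(vm, spec, 100.0, seed=3, crs=32632)
        effects = effects or {f"T{i+1}": 0.0 for i in range(design.n_treatments)}
        return FieldTruth(baseline=baseline, effects=effects,
                          noise_sd=noise_sd, variogram=vm)

    def test_noise_free_zero_effect_samples_equal_baseline(self):
        design = _design(4, 2, "interleaved")
        truth = self._truth(design)
        s = sample_harvest_tracks(truth, design, 10.0, 10.0, seed=1)
        row, col, inside = truth.baseline.cell_index(s.x, s.y)
        assert inside.all()
        assert np.array_equal(s.values, truth.baseline.values[row, col])

    def test_equal_per_treatment_counts(self):
        design = _design(6, 2, "interleaved")
        truth = self._truth(design)
        s = sample_harvest_tracks(truth, design, 5.0, 10.0, seed=1)
        n1 = sum(t == "T1" for t in s.treatments)
        n2 = sum(t == "T2" for t in s.treatments)
        assert n1 == n2

    def test_point_count_matches_combinatorial_oracle(self):
        # 200 x 120 m area, 20 m strips (10 strips), 5 m along x 10 m across
        area = StudyArea(box(0, 0, 200, 120), crs=32632)
        design = TrialDesign(area=area, n_treatments=2, strip_width=20.0,
                             layout="interleaved", orientation="columns")
        truth = self._truth(design)
        s = sample_harvest_tracks(truth, design, along_spacing=5.0,
                                  across_spacing=10.0, seed=1)
        n_strips = 200 // 20
        tracks_per_strip = math.floor(20.0 / 10.0)
        pts_per_track = math.floor(120.0 / 5.0)
        assert len(s) == n_strips * tracks_per_strip * pts_per_track

    def test_generator_determinism(self):
        design = _design(6, 2, "interleaved")
        truth = self._truth(design, noise_sd=2.0)
        a = sample_harvest_tracks(truth, design, 5.0, 10.0, seed=4)
        b = sample_harvest_tracks(truth, design, 5.0, 10.0, seed=4)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.values, b.values)

    def test_effects_added_per_strip(self):
        design = _design(4, 2, "interleaved")
        truth = self._truth(design, effects={"T1": 0.0, "T2": 300.0})
        s = sample_harvest_tracks(truth, design, 10.0, 10.0, seed=1)
        row, col, _ = truth.baseline.cell_index(s.x, s.y)
        base_at = truth.baseline.values[row, col]
        t2 = np.asarray([t == "T2" for t in s.treatments])
        assert np.allclose(s.values[t2] - base_at[t2], 300.0)
        assert np.allclose(s.values[~t2] - base_at[~t2], 0.0)

    def test_oversized_spacing_rejected(self):
        design = _design(4, 2, "interleaved")
        truth = self._truth(design)
        with pytest.raises(SimulationError):
            sample_harvest_tracks(truth, design, 5.0, 25.0, seed=1)

    def test_dropout_removes_points(self):
        design = _design(4, 2, "interleaved")
        truth = self._truth(design)
        full = sample_harvest_tracks(truth, design, 5.0, 10.0, seed=1)
        sparse = sample_harvest_tracks(truth, design, 5.0, 10.0, seed=1,
                                       dropout=0.3)
        assert len(sparse) < len(full)


class TestMakeTrial:
    def test_defaults_produce_realistic_density(self):
        s, area, truth = make_trial(seed=0)
        ha = area.polygon.area / 1e4
        density = len(s) / ha
        assert 418 <= density <= 1123  # harvester-monitor sample density band

    def test_trial_is_reproducible(self):
        s1, _, _ = make_trial(seed=5)
        s2, _, _ = make_trial(seed=5)
        assert np.array_equal(s1.values, s2.values)
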