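"""Box counting, fractal-dimension estimation, density and gradient profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_box_count
from myconet import (
    BoxCountCurve,
    BoxCountFractalEstimator,
    SyntheticNetworkParams,
    box_count,
    box_count_averaged,
    estimate_dimension,
    generate_gradient_series,
    generate_network,
    make_fixture,
    profile_gradient,
    surface_density,
)

LOG8_3 = np.log(8) / np.log(3)


class TestBoxCount:
    def test_filled_square_full_occupancy(self):
        mask = np.ones((640, 640), dtype=bool)
        curve = box_count(mask, (8, 64))
        assert curve.occupied_counts == (6400, 100)

    def test_single_pixel_always_one_box(self):
        mask = np.zeros((640, 640), dtype=bool)
        mask[123, 456] = True
        curve = box_count(mask, (8, 16, 32, 64))
        assert curve.occupied_counts == (1, 1, 1, 1)

    def test_sierpinski_closed_form_all_depths(self):
        fx = make_fixture("sierpinski_carpet", 729)
        sizes = [3**j for j in range(7)]
        curve = box_count(fx.image, sizes)
        assert curve.occupied_counts == tuple(8 ** (6 - j) for j in range(7))
        # and the naive per-box oracle agrees on the coarser grids
        assert list(curve.occupied_counts[3:]) == naive_box_count(fx.image, sizes[3:])

    def test_matches_naive_oracle_on_random_masks(self, rng):
        sizes = (3, 5, 8, 16, 32, 64)
        for _ in range(50):
            mask = rng.random((64, 64)) < rng.uniform(0.001, 0.5)
            got = box_count(mask, sizes).occupied_counts
            assert list(got) == naive_box_count(mask, sizes)

    def test_offset_grid_matches_naive_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((64, 64)) < 0.1
            for off in ((3, 0), (0, 5), (7, 7)):
                got = box_count(mask, (8, 16), offset=off).occupied_counts
                assert list(got) == naive_box_count(mask, (8, 16), offset=off)

    def test_non_divisor_grid_counts_partial_edge_boxes(self):
        mask = np.ones((10, 10), dtype=bool)
        curve = box_count(mask, [7])  # boxes: 7x7, 7x3, 3x7, 3x3
        assert curve.occupied_counts == (4,)

    def test_rectangular_mask_supported(self, rng):
        mask = rng.random((48, 96)) < 0.2
        assert list(box_count(mask, (8, 16)).occupied_counts) == naive_box_count(mask, (8, 16))

    def test_errors(self):
        mask = np.ones((32, 32), dtype=bool)
        with pytest.raises(ValueError, match="non-empty"):
            box_count(mask, [])
        with pytest.raises(ValueError, match="grid size"):
            box_count(mask, [64])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_nested_grid_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((64, 64)) < rng.uniform(0.01, 0.3)
        counts = box_count(mask, (8, 16, 32, 64)).occupied_counts
        assert counts[0] >= counts[1] >= counts[2] >= counts[3]

    def test_count_bounds(self, rng):
        mask = rng.random((64, 64)) < 0.05
        curve = box_count(mask, (8, 16, 32, 64))
        for s, n in zip(curve.grid_sizes_px, curve.occupied_counts):
            assert 0 <= n <= int(np.ceil(64 / s)) ** 2
            if mask.any():
                assert n >= 1


class TestEstimateDimension:
    @pytest.mark.parametrize(
        "name,size,grids,expected,exact_r2",
        [
            ("filled_square", 640, (8, 16, 32, 64), 2.0, True),
            ("hline", 640, (8, 16, 32, 64), 1.0, True),
            ("single_pixel", 640, (8, 16, 32, 64), 0.0, True),
            ("sierpinski_carpet", 729, (3, 9, 27, 81), LOG8_3, True),
        ],
    )
    def test_analytic_recovery(self, name, size, grids, expected, exact_r2):
        fx = make_fixture(name, size)
        est = estimate_dimension(box_count(fx.image, grids))
        assert est.dimension == pytest.approx(expected, abs=1e-9)
        if exact_r2:
            assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not est.flagged

    def test_zero_count_points_dropped_with_warning(self):
        curve = BoxCountCurve((8, 16, 32, 64), (100, 25, 6, 0), (640, 640))
        with pytest.warns(UserWarning, match="N\\(s\\)=0"):
            est = estimate_dimension(curve)
        assert est.n_points_used == 3

    def test_fewer_than_two_points_errors(self):
        with pytest.raises(ValueError, match="distinct grid sizes"):
            estimate_dimension(BoxCountCurve((8, 16), (5, 0), (64, 64)))

    def test_offset_sensitivity_small_on_carpet(self):
        fx = make_fixture("sierpinski_carpet", 729)
        dims = []
        for anchor in ((0, 0), (0, 729), (729, 0), (729, 729)):
            counts = [
                box_count(fx.image, [s], offset=(anchor[0] % s, anchor[1] % s)).occupied_counts[0]
                for s in (3, 9, 27, 81)
            ]
            dims.append(
                estimate_dimension(BoxCountCurve((3, 9, 27, 81), tuple(counts), (729, 729))).dimension
            )
        assert max(dims) - min(dims) < 0.05

    def test_estimator_class_fitted_attributes(self):
        fx = make_fixture("sierpinski_carpet", 729)
        est = BoxCountFractalEstimator(grid_sizes_px=(3, 9, 27, 81)).fit(fx.image)
        assert est.dimension_ == pytest.approx(LOG8_3, abs=1e-9)
        assert est.r_squared_ == pytest.approx(1.0)
        assert est.curve_.occupied_counts[0] == 8**5
        # averaged anchoring agrees on an aligned, grid-divisible raster
        est4 = BoxCountFractalEstimator((3, 9, 27, 81), anchoring="average4").fit(fx.image)
        assert est4.dimension_ == pytest.approx(est.dimension_, abs=1e-12)

    def test_get_set_params_roundtrip(self):
        est = BoxCountFractalEstimator()
        est.set_params(grid_sizes_px=(4, 8), anchoring="average4")
        assert est.get_params()["grid_sizes_px"] == (4, 8)


class TestSurfaceDensity:
    def test_filled_empty_half(self):
        full = np.ones((640, 640), dtype=bool)
        empty = np.zeros((640, 640), dtype=bool)
        half = np.zeros((640, 640), dtype=bool)
        half[:, :320] = True
        assert surface_density(full).coverage_percent == 100.0
        assert surface_density(empty).coverage_percent == 0.0
        assert surface_density(half).coverage_percent == 50.0

    def test_exact_pixel_ratio(self, rng):
        mask = rng.random((100, 100)) < 0.07
        d = surface_density(mask)
        assert d.coverage_frac == mask.sum() / mask.size


class TestGradientProfile:
    def test_filled_rois_are_flat(self):
        full = np.ones((640, 640), dtype=bool)
        prof = profile_gradient([(1, full), (2, full), (3, full)], source="clean_mask",
                                min_cluster_px=1, smoothing_radius_px=0)
        assert [d.dimension for d in prof.dimensions] == pytest.approx([2.0, 2.0, 2.0])
        assert [d.coverage_percent for d in prof.densities] == pytest.approx([100.0] * 3)

    @pytest.mark.parametrize("fracs", [[0.04, 0.06, 0.08], [0.08, 0.06, 0.04]])
    def test_synthetic_series_density_monotone(self, fracs):
        series = generate_gradient_series(SyntheticNetworkParams(rng_seed=13), 3, fracs)
        prof = profile_gradient(
            [(im.metadata["label"], im.pixels) for im in series], smoothing_radius_px=0
        )
        dens = [d.coverage_percent for d in prof.densities]
        diffs = np.diff(dens)
        if fracs[0] < fracs[-1]:
            assert (diffs > 0).all()
        else:
            assert (diffs < 0).all()

    def test_tidy_table_columns(self):
        full = np.ones((128, 128), dtype=bool)
        prof = profile_gradient([(1, full)], grid_sizes_px=(8, 16), source="clean_mask",
                                min_cluster_px=1, smoothing_radius_px=0)
        df = prof.to_frame()
        assert {"label", "D_m", "r_squared", "coverage_percent", "N_s8", "N_s16"} <= set(df.columns)

    def test_empty_roi_list_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            profile_gradient([])

    def test_dimension_not_decreasing_with_coverage(self):
        # seed-averaged D_m should not drop as target coverage rises
        means = []
        for target in (0.03, 0.06, 0.09):
            dims = []
            for seed in range(10):
                img = generate_network(
                    SyntheticNetworkParams(target_coverage_frac=target, rng_seed=seed)
                )
                prof = profile_gradient([(1, img.pixels)], smoothing_radius_px=0)
                dims.append(prof.dimensions[0].dimension)
            means.append(np.mean(dims))
        assert means[0] <= means[1] <= means[2]
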