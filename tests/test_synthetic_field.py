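import numpy as np
import pytest

from phenoheight import synthetic_field as sf
from phenoheight.pointcloud import GROUND, NOISE


class TestTerrain:
    def test_zero_relief_is_flat(self, small_design):
        t = sf.generate_terrain(small_design, 0.0, 0.1, seed=1)
        assert np.ptp(t.values) == 0.0

    def test_deterministic_given_seed(self, small_design):
        a = sf.generate_terrain(small_design, 0.4, 0.1, seed=5)
        b = sf.generate_terrain(small_design, 0.4, 0.1, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_relief_bounds_range(self, small_design):
        t = sf.generate_terrain(small_design, 0.5, 0.1, seed=2)
        assert np.ptp(t.values) <= 2 * 0.5 + 1e-12

    def test_bad_cell_rejected(self, small_design):
        with pytest.raises(ValueError):
            sf.generate_terrain(small_design, 0.1, 0.0, seed=1)


class TestGrowthTruth:
    def test_heights_monotone_and_rates_ordered(self):
        truth = sf.generate_growth_truth(419, 5, 5, separation=4.0, seed=3)
        assert np.all(truth.heights >= 0)
        assert np.all(np.diff(truth.heights, axis=1) >= 0)
        rates = truth.curve_params[:, 1]
        cluster_rate_means = [
            rates[truth.cluster_id == c].mean() for c in range(5)
        ]
        assert np.all(np.diff(cluster_rate_means) > 0)
        assert len(np.unique(truth.cluster_id)) == 5

    def test_single_cluster_shares_rate_distribution(self):
        truth = sf.generate_growth_truth(50, 5, 1, separation=4.0, seed=4)
        assert np.all(truth.cluster_id == 0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sf.generate_growth_truth(3, 5, 5, seed=0)
        with pytest.raises(ValueError):
            sf.generate_growth_truth(10, 1, 2, seed=0)
        with pytest.raises(ValueError):
            sf.generate_growth_truth(10, 5, 0, seed=0)

    def test_genetic_shift_moves_asymptote(self):
        truth = sf.generate_growth_truth(10, 5, 2, seed=5)
        shift = np.full(10, 0.1)
        moved = sf.apply_genetic_effects(truth, shift)
        np.testing.assert_allclose(
            moved.curve_params[:, 0], truth.curve_params[:, 0] + 0.1
        )


class TestPointCloud:
    def test_density_matches_poisson_expectation(
        self, small_design, small_terrain, small_growth
    ):
        sensor = sf.SensorConfig(point_density=100.0, canopy_cover=0.0, seed=7)
        cloud = sf.generate_point_cloud(
            small_terrain, small_design, small_growth, 0, sensor
        )
        xmin, ymin, xmax, ymax = small_design.extent()
        expect = 100.0 * (xmax - xmin) * (ymax - ymin)
        assert abs(len(cloud) - expect) < 5 * np.sqrt(expect)

    def test_no_canopy_points_track_terrain(
        self, small_design, small_terrain, small_growth
    ):
        sensor = sf.SensorConfig(
            point_density=50.0, noise_sd=0.01, outlier_rate=0.0, canopy_cover=0.0, seed=8
        )
        cloud = sf.generate_point_cloud(
            small_terrain, small_design, small_growth, 2, sensor
        )
        dz = cloud.z - small_terrain.sample(cloud.x, cloud.y)
        # Gaussian noise: nearly all within 3 sigma, everything within 6
        assert np.quantile(np.abs(dz), 0.99) <= 3.0 * 0.01
        assert np.all(np.abs(dz) <= 6.0 * 0.01)
        assert np.all(cloud.truth_class == GROUND)

    def test_noiseless_canopy_height_exact(
        self, small_design, small_terrain, small_growth, noiseless_sensor
    ):
        t = 4
        cloud = sf.generate_point_cloud(
            small_terrain, small_design, small_growth, t, noiseless_sensor
        )
        # within each plot, canopy-top minus local ground equals true height
        for i in range(small_design.n_plots):
            xmin, ymin, xmax, ymax = sf.canopy_rectangle(small_design, i, 0.6)
            inside = (
                (cloud.x >= xmin) & (cloud.x <= xmax)
                & (cloud.y >= ymin) & (cloud.y <= ymax)
            )
            if not inside.any():
                continue
            dz = cloud.z[inside] - small_terrain.sample(cloud.x[inside], cloud.y[inside])
            np.testing.assert_allclose(dz, small_growth.heights[i, t], atol=1e-9)

    def test_outliers_labelled_noise(
        self, small_design, small_terrain, small_growth
    ):
        sensor = sf.SensorConfig(outlier_rate=0.05, seed=9)
        cloud = sf.generate_point_cloud(
            small_terrain, small_design, small_growth, 1, sensor
        )
        frac = np.mean(cloud.truth_class == NOISE)
        assert 0.03 < frac < 0.07


class TestRgbDsm:
    def test_low_cover_leaves_soil_majority(
        self, small_design, small_terrain, small_growth
    ):
        sensor = sf.SensorConfig(noise_sd=0.0, canopy_cover=0.2, seed=10)
        dsm = sf.generate_dsm(small_terrain, small_design, small_growth, 2, sensor, 0.1)
        x0, y0, x1, y1 = small_design.plot_rectangle(0)
        xs = dsm.x_centers()
        ys = dsm.y_centers()
        sel = np.ix_((ys > y0) & (ys < y1), (xs > x0) & (xs < x1))
        plot_vals = dsm.values[sel]
        X, Y = np.meshgrid(xs[(xs > x0) & (xs < x1)], ys[(ys > y0) & (ys < y1)])
        terr = small_terrain.sample(X, Y)
        soil_frac = np.mean(np.abs(plot_vals - terr) < 1e-9)
        assert soil_frac >= 0.70

    def test_noiseless_plot_range_equals_height(self, small_design, small_growth):
        flat = sf.generate_terrain(small_design, 0.0, 0.05, seed=1)
        sensor = sf.SensorConfig(noise_sd=0.0, canopy_cover=0.5, seed=10)
        t = 3
        dsm = sf.generate_dsm(flat, small_design, small_growth, t, sensor, 0.05)
        x0, y0, x1, y1 = small_design.plot_rectangle(0)
        xs = dsm.x_centers()
        ys = dsm.y_centers()
        sel = np.ix_((ys > y0) & (ys < y1), (xs > x0) & (xs < x1))
        assert np.ptp(dsm.values[sel]) == pytest.approx(small_growth.heights[0, t])

    def test_deterministic(self, small_design, small_terrain, small_growth, noisy_sensor):
        a = sf.generate_dsm(small_terrain, small_design, small_growth, 1, noisy_sensor, 0.1)
        b = sf.generate_dsm(small_terrain, small_design, small_growth, 1, noisy_sensor, 0.1)
        np.testing.assert_array_equal(a.values, b.values)

    def test_cell_larger_than_plot_rejected(
        self, small_design, small_terrain, small_growth, noisy_sensor
    ):
        with pytest.raises(ValueError):
            sf.generate_dsm(small_terrain, small_design, small_growth, 0, noisy_sensor, 5.0)


class TestGenotypes:
    def test_shape_and_missingness(self):
        truth = sf.GenotypeTruth(h2=0.5)
        G = sf.generate_genotypes(419, 5000, missing_rate=0.0, truth=truth, seed=1)
        assert G.dosages.shape == (419, 5000)
        assert not (G.dosages == -1).any()
        G2 = sf.generate_genotypes(50, 500, missing_rate=0.1, truth=truth, seed=1)
        assert abs((G2.dosages == -1).mean() - 0.1) < 0.01

    def test_no_structure_without_drift(self):
        truth = sf.GenotypeTruth(h2=0.5, n_subpop=2, fst_like=0.0)
        G = sf.generate_genotypes(200, 800, missing_rate=0.0, truth=truth, seed=2)
        from sklearn.decomposition import PCA

        X = G.imputed()
        pc1 = PCA(n_components=1).fit_transform(X - X.mean(axis=0)).ravel()
        subpop = np.resize([0, 1], 200)
        # PC1 should not separate the nominal subpopulations
        from scipy import stats

        _, p = stats.ttest_ind(pc1[subpop == 0], pc1[subpop == 1])
        assert p > 0.01

    def test_structure_with_drift(self, small_genotypes):
        G, _ = small_genotypes
        from sklearn.decomposition import PCA
        from scipy import stats

        X = G.imputed()
        pc1 = PCA(n_components=1).fit_transform(X - X.mean(axis=0)).ravel()
        subpop = np.resize([0, 1], G.n_samples)
        _, p = stats.ttest_ind(pc1[subpop == 0], pc1[subpop == 1])
        assert p < 1e-6

    def test_bad_maf_range_rejected(self):
        with pytest.raises(ValueError):
            sf.generate_genotypes(10, 10, maf_range=(0.0, 0.6), seed=0)


class TestPhenotypes:
    def test_noiseless_limit_linear_in_causal_dosages(self, small_genotypes):
        G, _ = small_genotypes
        truth = sf.GenotypeTruth(
            causal_indices=[5, 100], effect_sizes=[0.05, -0.03], h2=1.0
        )
        table, genetic = sf.generate_phenotypes(G, truth, n_reps=1, seed=3, poly_frac=0.0)
        expect = G.imputed()[:, [5, 100]] @ np.array([0.05, -0.03])
        np.testing.assert_allclose(table["value"].to_numpy(), expect, atol=1e-12)

    def test_replicate_count(self, small_genotypes):
        G, truth = small_genotypes
        table, _ = sf.generate_phenotypes(G, truth, n_reps=3, seed=4)
        assert len(table) == 3 * G.n_samples

    def test_realized_heritability(self):
        truth = sf.GenotypeTruth(
            causal_indices=[10], effect_sizes=[0.08], h2=0.5, n_subpop=2, fst_like=0.1
        )
        G = sf.generate_genotypes(419, 1000, missing_rate=0.0, truth=truth, seed=5)
        table, genetic = sf.generate_phenotypes(G, truth, n_reps=1, seed=6)
        resid = table["value"].to_numpy() - genetic - (
            table["value"].to_numpy() - genetic
        ).mean()
        h2_realized = genetic.var() / (genetic.var() + resid.var())
        assert abs(h2_realized - 0.5) < 0.05

    def test_causal_out_of_range_rejected(self, small_genotypes):
        G, _ = small_genotypes
        bad = sf.GenotypeTruth(causal_indices=[10**6], effect_sizes=[0.1], h2=0.5)
        with pytest.raises(ValueError):
            sf.generate_phenotypes(G, bad, seed=0)
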