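import numpy as np
import pytest

from phenoheight import synthetic_field as sf


@pytest.fixture(scope="session")
def small_design() -> sf.FieldDesign:
    return sf.FieldDesign(3, 2)


@pytest.fixture(scope="session")
def small_terrain(small_design) -> "sf.RasterGrid":
    return sf.generate_terrain(small_design, relief_amplitude=0.3, cell=0.05, seed=11)


@pytest.fixture(scope="session")
def small_growth(small_design) -> sf.GrowthTruth:
    return sf.generate_growth_truth(
        small_design.n_plots, n_times=5, n_clusters=3, separation=4.0, seed=12
    )


@pytest.fixture(scope="session")
def noiseless_sensor() -> sf.SensorConfig:
    return sf.SensorConfig(
        point_density=100.0, noise_sd=0.0, outlier_rate=0.0, canopy_cover=0.6, seed=13
    )


@pytest.fixture(scope="session")
def noisy_sensor() -> sf.SensorConfig:
    return sf.SensorConfig(
        point_density=100.0, noise_sd=0.02, outlier_rate=0.01, canopy_cover=0.6, seed=13
    )


@pytest.fixture(scope="session")
def small_genotypes():
    truth = sf.GenotypeTruth(h2=0.5, n_subpop=2, fst_like=0.1)
    G = sf.generate_genotypes(
        60, 400, maf_range=(0.05, 0.5), missing_rate=0.05, truth=truth, seed=21
    )
    return G, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
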