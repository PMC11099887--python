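import pytest

from lipidccs.reference import build_reference_library
from lipidccs.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def reference_lib():
    """The packaged synthetic U13C reference library."""
    return build_reference_library()


@pytest.fixture(scope="session")
def clean_sim():
    """Default study-condition simulation without planted violations."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def violated_sim():
    """Simulation with the four curation-filter violation types planted."""
    return simulate_dataset(
        SimulationConfig(
            seed=42,
            n_high_ppm=3,
            n_single_dilution=2,
            n_non_coeluting=1,
            n_high_rsd=1,
        )
    )


@pytest.fixture(scope="session")
def noise_free_sim():
    """Noise-free simulation with an exact affine bias (1.01, -2.0 A^2)."""
    return simulate_dataset(
        SimulationConfig(seed=3, noise_sd_pct=0.0, bias_slope=1.01, bias_intercept=-2.0)
    )
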