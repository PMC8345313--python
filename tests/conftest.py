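import warnings

import numpy as np
import pytest

import svdburden as sv

# boundary-clamp warnings from degenerate simulated draws are expected noise
warnings.filterwarnings("ignore", message="latent correlation at boundary")


@pytest.fixture(scope="session")
def defaults():
    return sv.default_generating_parameters()


@pytest.fixture(scope="session")
def cohort_20k(defaults):
    """Moderate-precision cohort shared across module tests."""
    tab = sv.generate_cohort(defaults, 20_000, 11)
    return sv.derive_visual_ratings(tab, defaults, 12)


@pytest.fixture(scope="session")
def cohort_540(defaults):
    """Study-scale cohort (single draw)."""
    tab = sv.generate_cohort(defaults, 540, 17)
    return sv.derive_visual_ratings(tab, defaults, 18)


@pytest.fixture(scope="session")
def prepared_540(cohort_540):
    return sv.prepare_analysis_table(cohort_540)


def simulate_bivariate_categorical(rho, tau_x, tau_y, n, seed):
    """Threshold a bivariate normal draw into category codes."""
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = np.searchsorted(np.atleast_1d(tau_x), z[:, 0]).astype(float)
    y = np.searchsorted(np.atleast_1d(tau_y), z[:, 1]).astype(float)
    return x, y, z
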