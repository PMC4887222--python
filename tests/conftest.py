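import numpy as np
import pytest

import dpca


@pytest.fixture(scope="session")
def small_population():
    """Balanced synthetic population with one latent per marginalization."""
    data, truth = dpca.generate_population(N=20, S=3, Q=2, T=20, K=5,
                                           snr=2.0, seed=11)
    return data, truth


@pytest.fixture(scope="session")
def small_fit(small_population):
    data, truth = small_population
    psth = dpca.compute_psths(data, center=True)
    mset = dpca.decompose(psth)
    noise = dpca.estimate_noise_covariance(data)
    model = dpca.fit(psth, mset, noise=noise, q_per_label=3)
    return data, truth, psth, mset, noise, model


def random_centered_psth(rng, N=8, S=3, Q=2, T=10):
    """Random centered PSTH tensor (no structure)."""
    arr = rng.standard_normal((N, S, Q, T))
    arr -= arr.mean(axis=(1, 2, 3), keepdims=True)
    return dpca.PsthTensor(values=arr, time=np.arange(T, dtype=float),
                           centered=True, means=np.zeros(N))
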