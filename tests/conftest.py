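import numpy as np
import pytest

# Fitted transcriptome mixture parameter sets used across tests:
# (lambda, mu, sigma) per component, low-CpG component first.
SEAGRASS_MIXTURES = {
    "p_oceanica": ((0.661, 0.339), (0.476, 0.650), (0.127, 0.214)),
    "c_nodosa": ((0.663, 0.337), (0.553, 0.778), (0.186, 0.241)),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def draw_mixture(rng, lam, mu, sigma, n):
    comp = rng.choice(len(lam), size=n, p=lam)
    return rng.normal(np.asarray(mu)[comp], np.asarray(sigma)[comp]), comp
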