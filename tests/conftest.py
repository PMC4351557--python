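import numpy as np
import pytest

from hydrospec import RenewalParams, build_alternating_renewal, ensemble_psd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def renewal_ensemble():
    """Reference alternating-renewal ensemble (alpha=1.2, cutoffs 60/1000 ps).

    Shared across spectral and acceptance tests; 32 series x 2^16 frames
    keeps the whole-suite runtime modest while leaving ~1.5 decades above
    the plateau.
    """
    params = [RenewalParams(n_steps=2**16, seed=5000 + i) for i in range(32)]
    return [build_alternating_renewal(p) for p in params]


@pytest.fixture(scope="session")
def renewal_psd(renewal_ensemble):
    return ensemble_psd(renewal_ensemble, 1.0)
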