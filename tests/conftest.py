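import numpy as np
import pandas as pd
import pytest

from mahex import SimConfig, default_contrasts, generate_chips


@pytest.fixture(scope="session")
def small_config():
    """A chip small enough for fast unit tests but with all six
    samples and the seven standard contrasts."""
    return SimConfig(n_probesets=400, probes_per_set=5, de_fraction=0.05, seed=11)


@pytest.fixture(scope="session")
def small_chips(small_config):
    return generate_chips(small_config)


@pytest.fixture(scope="session")
def fullscale_contrast3():
    """Full-scale single-contrast study: 42,800 probe sets, ~257
    probe sets with a planted 2.0 log2 shift in the treated sample of
    the IBD-colonoid LPS contrast.  Session-scoped because the run
    feeds several acceptance checks."""
    from mahex import compute_contrast, rma

    cdef = default_contrasts()[2]
    config = SimConfig(seed=0, contrasts=(cdef,))
    probes, truth = generate_chips(config)
    expr, fit, qc = rma(probes)
    ma = compute_contrast(expr, cdef)
    return config, truth, ma


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
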