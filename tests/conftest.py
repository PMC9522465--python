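import numpy as np
import pytest

import vidqc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_session():
    """20 s noise-free circling-blob session with 50 injected duplicates."""
    spec = vidqc.SessionSpec(duration_s=20.0, noise_sigma=0.0, n_duplicates=50, seed=7)
    stream, manifest = vidqc.render_session(spec)
    return spec, stream, manifest


@pytest.fixture(scope="session")
def clean_session():
    """20 s noise-free session with no injected defects."""
    spec = vidqc.SessionSpec(duration_s=20.0, noise_sigma=0.0, seed=11)
    stream, manifest = vidqc.render_session(spec)
    return spec, stream, manifest
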