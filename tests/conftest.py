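import numpy as np
import pytest

import tsgeeg as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def corr_sessions():
    """Two-subject cohort whose classes differ only in correlation structure."""
    cfg = tg.SyntheticCohortConfig(
        class_specs=tg.correlation_effect_specs(), n_subjects=2, n_channels=6,
        duration_per_class=150.0, seed=11,
    )
    return tg.build_sessions(tg.generate_cohort(cfg))


@pytest.fixture(scope="session")
def small_recording():
    """One short, cheap synthetic recording (6 channels, 20 s)."""
    specs = tg.null_specs()
    return tg.generate_recording(specs[0], 6, 128.0, 20.0, seed=7)


def windows_with_correlation(C: np.ndarray, w: int, rng) -> np.ndarray:
    """A window whose *sample* Pearson correlation matrix is exactly C.

    Builds column-centered orthonormal directions Q (Gram-Schmidt of
    centered Gaussian columns) and returns ``chol(C) @ Q.T``; the centered
    Gram matrix of the rows is then exactly C.
    """
    n_c = C.shape[0]
    G = rng.standard_normal((w, n_c))
    G -= G.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(G)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n_c))
    return L @ Q.T
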