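import numpy as np
import pytest

import eegsilence as es


@pytest.fixture(scope="session")
def small_geometry():
    """Compact spherical-head geometry shared across tests (64 ch, 200 src)."""
    montage = es.make_montage(64)
    sources = es.make_source_space(200)
    lf = es.build_spherical_leadfield(montage, sources, es.synthetic_data.HEAD_RADIUS_MM)
    return montage, sources, lf


@pytest.fixture(scope="session")
def study_geometry():
    """Study-sized geometry (128 ch, 804 src) built once per session."""
    montage = es.make_montage(128)
    sources = es.make_source_space(804)
    lf = es.build_spherical_leadfield(montage, sources, es.synthetic_data.HEAD_RADIUS_MM)
    return montage, sources, lf


def make_orthogonal_leadfield(n=16, p=8):
    """Leadfield with exactly orthonormal, average-referenced columns."""
    rng = np.random.default_rng(42)
    M = rng.standard_normal((n, p + 1))
    M -= M.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(M)
    A = Q[:, 1:p + 1]  # column 0 absorbs any mean component
    A -= A.mean(axis=0, keepdims=True)
    A /= np.linalg.norm(A, axis=0)
    return es.normalize_leadfield(A)


@pytest.fixture()
def orthogonal_leadfield():
    return make_orthogonal_leadfield()
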