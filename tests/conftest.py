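"""Shared fixtures: acquisition schemes and small phantoms."""

import numpy as np
import pytest

from glymphkit import AcquisitionScheme, make_scheme


@pytest.fixture(scope="session")
def hcpa_scheme():
    return make_scheme("hcpa", seed=0)


@pytest.fixture(scope="session")
def adni_scheme():
    return make_scheme("adni", seed=0)


@pytest.fixture(scope="session")
def tiny_scheme():
    """Minimal two-shell scheme for fast analytic checks."""
    axes = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0],
                     [1, 1, 0] / np.sqrt(2), [1, 0, 1] / np.sqrt(2),
                     [0, 1, 1] / np.sqrt(2), [1, -1, 0] / np.sqrt(2),
                     [1, 0, -1] / np.sqrt(2), [0, 1, -1] / np.sqrt(2)])
    bvecs = np.vstack([[0, 0, 0], axes, axes])
    bvals = np.array([0.0] + [1000.0] * 9 + [2500.0] * 9)
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def random_psd_tensor(rng, scale=1e-3):
    """Random symmetric PSD 3x3 tensor with eigenvalues O(scale)."""
    A = rng.standard_normal((3, 3))
    return (A @ A.T) * scale / 3.0
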