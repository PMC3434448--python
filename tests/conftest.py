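import numpy as np
import pandas as pd
import pytest

import cortical_layout as cl


@pytest.fixture(scope="session")
def atlas():
    return cl.load_reference_atlas()


@pytest.fixture(scope="session")
def small_dataset(atlas):
    """Small default-structure synthetic dataset (2 subjects, 3 voxels/area)."""
    cfg = cl.SynthConfig(n_subjects=2, voxels_per_area=3, seed=11)
    return cl.simulate_dataset(atlas, cfg)


@pytest.fixture(scope="session")
def small_innovations(small_dataset):
    """Prewhitened version of the small dataset (fast estimator)."""
    return cl.prewhiten_dataset(small_dataset, method="hannan_rissanen")


@pytest.fixture
def toy_atlas():
    """Six-area bilateral toy atlas with a clean anterior-posterior axis."""
    frame = pd.DataFrame(
        {
            "label": ["L_A", "L_B", "L_C", "R_A", "R_B", "R_C"],
            "hemisphere": ["left"] * 3 + ["right"] * 3,
            "x": [-40.0, -42.0, -38.0, 40.0, 42.0, 38.0],
            "y": [30.0, 0.0, -30.0, 30.0, 0.0, -30.0],
            "z": [20.0, 25.0, 15.0, 20.0, 25.0, 15.0],
            "volume": [1000.0] * 6,
        }
    )
    return cl.AreaAtlas(frame)


def orthonormal_zero_mean(n_vectors: int, length: int, seed: int = 0) -> np.ndarray:
    """Rows: zero-mean, unit-norm, mutually orthogonal series.

    Linear combinations of these rows have exactly the sample Pearson
    correlations implied by their coefficients, which makes hand-computed
    correlation examples exact.
    """
    rng = np.random.default_rng(seed)
    mat = rng.standard_normal((length, n_vectors + 1))
    mat[:, 0] = 1.0  # constant direction; projected out by QR ordering
    q, _ = np.linalg.qr(mat)
    return q[:, 1:].T  # orthogonal to the constant => zero mean
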