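import numpy as np
import pytest

from orlrs.synthetic import SubspaceSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noisy_outlier_case():
    """Default study instance: 3 subspaces, dense noise, 10% extreme outliers."""
    spec = SubspaceSpec(
        ambient_dim=60,
        samples_per_cluster=[15, 15, 15],
        subspace_dims=[3, 3, 3],
        noise_sd=0.05,
        outlier_fraction=0.10,
        outlier_scale=10.0,
        orthogonalize=True,
        seed=3,
    )
    return generate(spec)


def mid_theta(X, mask) -> float:
    """Threshold between the clean and outlier column-norm scales."""
    norms = np.linalg.norm(X.values, axis=0)
    return float(np.sqrt(norms[~mask].max() * norms[mask].min()))
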