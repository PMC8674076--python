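"""Synthetic union-of-subspaces fixtures.

Generates data with exactly the structure the solver assumes: each cluster's
samples are random linear combinations of an r_i-dimensional orthonormal
basis of the m-dimensional gene space, plus dense i.i.d. Gaussian noise,
plus an optional fraction of extreme-outlier columns whose norms are pegged
to a multiple of the median clean column norm.  Ground-truth labels and the
outlier mask are returned alongside the matrix.

The generator deliberately does *not* emulate expression-platform realism
(nonnegativity, counts, heavy tails): it tests the algorithm's own model,
not biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ExpressionMatrix, IndicatorSet

__all__ = ["SubspaceSpec", "generate", "clean_recovery_case"]


@dataclass
class SubspaceSpec:
    """Parameters of a union-of-subspaces instance.

    ``outlier_scale`` multiplies the median clean column norm to set the
    exact Euclidean norm of every injected outlier column; with
    ``orthogonalize`` the cluster bases are mutually orthogonal (requires
    Σ r_i ≤ m).
    """

    ambient_dim: int
    samples_per_cluster: list[int] = field(default_factory=lambda: [15, 15, 15])
    subspace_dims: list[int] = field(default_factory=lambda: [3, 3, 3])
    noise_sd: float = 0.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 10.0
    orthogonalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_cluster) != len(self.subspace_dims):
            raise ValueError("samples_per_cluster and subspace_dims disagree in length")
        if any(n_i < 1 for n_i in self.samples_per_cluster):
            raise ValueError("every cluster needs at least one sample")
        if any(r_i < 1 or r_i > self.ambient_dim for r_i in self.subspace_dims):
            raise ValueError("subspace dims must lie in [1, ambient_dim]")
        if self.orthogonalize and sum(self.subspace_dims) > self.ambient_dim:
            raise ValueError(
                "orthogonal bases infeasible: sum of subspace dims "
                f"{sum(self.subspace_dims)} exceeds ambient dim {self.ambient_dim}"
            )
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not self.outlier_scale > 0:
            raise ValueError("outlier_scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def c(self) -> int:
        return len(self.samples_per_cluster)

    @property
    def n(self) -> int:
        return sum(self.samples_per_cluster)


def generate(
    spec: SubspaceSpec,
) -> tuple[ExpressionMatrix, IndicatorSet, np.ndarray]:
    """Draw one instance: (matrix, ground-truth labels, outlier mask).

    Deterministic given ``spec.seed``.  Outlier columns *replace* clean ones:
    a uniformly random direction scaled so the column norm equals
    ``outlier_scale`` × median clean column norm, which places them past any
    sensible capped-norm threshold by construction.
    """
    rng = np.random.default_rng(spec.seed)
    m, n, c = spec.ambient_dim, spec.n, spec.c

    if spec.orthogonalize:
        joint = np.linalg.qr(rng.standard_normal((m, sum(spec.subspace_dims))))[0]
        splits = np.cumsum(spec.subspace_dims)[:-1]
        bases = np.split(joint, splits, axis=1)
    else:
        bases = [
            np.linalg.qr(rng.standard_normal((m, r)))[0] for r in spec.subspace_dims
        ]

    blocks, labels = [], []
    for i, (U, n_i) in enumerate(zip(bases, spec.samples_per_cluster)):
        coef = rng.standard_normal((U.shape[1], n_i))
        blocks.append(U @ coef)
        labels.extend([i] * n_i)
    X = np.concatenate(blocks, axis=1)
    labels = np.asarray(labels, dtype=int)

    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)

    mask = np.zeros(n, dtype=bool)
    n_out = int(round(spec.outlier_fraction * n))
    if n_out > 0:
        median_norm = float(np.median(np.linalg.norm(X, axis=0)))
        idx = rng.choice(n, size=n_out, replace=False)
        for j in idx:
            d = rng.standard_normal(m)
            X[:, j] = d * (spec.outlier_scale * median_norm / np.linalg.norm(d))
        mask[idx] = True

    xm = ExpressionMatrix(
        values=X,
        gene_ids=[f"g{i + 1}" for i in range(m)],
        sample_ids=[f"s{j + 1}" for j in range(n)],
    )
    return xm, IndicatorSet(labels=labels, c=c), mask


def clean_recovery_case(seed: int = 0) -> tuple[ExpressionMatrix, IndicatorSet]:
    """Canonical noiseless fixture: 3 mutually orthogonal 3-dim subspaces.

    m = 60 genes, 15 samples per cluster, no noise, no outliers — a case
    where subspace recovery is information-theoretically trivial and the
    solver is expected to reach ACC = 1.
    """
    spec = SubspaceSpec(
        ambient_dim=60,
        samples_per_cluster=[15, 15, 15],
        subspace_dims=[3, 3, 3],
        noise_sd=0.0,
        outlier_fraction=0.0,
        orthogonalize=True,
        seed=seed,
    )
    xm, truth, _ = generate(spec)
    return xm, truth
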