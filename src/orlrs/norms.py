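"""Matrix-norm primitives used by the ORLRS block updates.

The solver repeatedly needs Schatten p-norms, the column-wise L2,1 and
capped norms, and fractional powers of symmetric PSD matrices (which show
up as IRLS reweighting matrices).  Everything here is dense and exact up
to an explicit eigenvalue ridge; the ridge is the standard IRLS smoothing
device for negative powers of rank-deficient matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegularizedPowerSpec",
    "schatten_p_norm",
    "low_rank_term",
    "l21_norm",
    "capped_norm",
    "column_norms",
    "sym_power",
    "effective_ridge",
]

#: absolute floor for the eigenvalue ridge, below which negative powers
#: overflow into meaningless magnitudes.
RIDGE_FLOOR = 1e-12

#: relative symmetry tolerance accepted by :func:`sym_power`.
SYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class RegularizedPowerSpec:
    """Exponent and eigenvalue ridge for a regularized symmetric matrix power.

    ``exponent`` is the power q applied to the (clamped, ridged) eigenvalues;
    ``ridge`` is added to every eigenvalue before raising to q.  A strictly
    positive ridge is mandatory for negative exponents, where the power of a
    possibly singular matrix is otherwise undefined.
    """

    exponent: float
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.ridge < 0:
            raise ValueError(f"ridge must be >= 0, got {self.ridge}")
        if self.exponent < 0 and self.ridge <= 0:
            raise ValueError(
                "a positive ridge is required for negative exponents "
                f"(exponent={self.exponent}, ridge={self.ridge})"
            )


def _as_finite_2d(G, name: str = "matrix") -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {G.shape}")
    if not np.all(np.isfinite(G)):
        raise ValueError(f"{name} contains non-finite entries")
    return G


def schatten_p_norm(G, p: float) -> float:
    """Schatten p-norm ``(sum_i sigma_i(G)^p)^(1/p)`` over all singular values.

    p = 1 is the nuclear norm, p = 2 the Frobenius norm.  0 < p < 1 gives the
    tighter (nonconvex) rank surrogates the solver relies on.
    """
    G = _as_finite_2d(G)
    if not p > 0:
        raise ValueError(f"p must be > 0, got {p}")
    sigma = np.linalg.svd(G, compute_uv=False)
    return float(np.sum(sigma**p) ** (1.0 / p))


def low_rank_term(G, k: float) -> float:
    """Tr((Gᵀ G)^k) = sum_i sigma_i(G)^(2k), the per-cluster low-rank penalty.

    Under the convention p = 2k this equals (‖G‖_{S_p}^k)²; for k = 1 it is
    the squared Frobenius norm.
    """
    G = _as_finite_2d(G)
    if not 0 < k <= 1:
        raise ValueError(f"k must be in (0, 1], got {k}")
    if G.shape[1] == 0:
        return 0.0
    sigma = np.linalg.svd(G, compute_uv=False)
    return float(np.sum(sigma ** (2.0 * k)))


def column_norms(E) -> np.ndarray:
    """Euclidean norm of every column of ``E`` (length-n vector)."""
    E = _as_finite_2d(E)
    return np.linalg.norm(E, axis=0)


def l21_norm(E) -> float:
    """L2,1 norm: the sum of Euclidean column norms (column-sparsity prior)."""
    return float(column_norms(E).sum())


def capped_norm(E, theta: float) -> float:
    """Capped norm sum_j min(‖E_j‖₂, θ).

    Columns whose norm exceeds θ pay the flat cost θ — extreme outliers stop
    influencing the fit entirely.  θ = +inf recovers the L2,1 norm exactly.
    """
    if not theta > 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    return float(np.minimum(column_norms(E), theta).sum())


def effective_ridge(lam_max: float, ridge_rel: float) -> float:
    """Absolute eigenvalue ridge: ``ridge_rel`` × largest eigenvalue, floored."""
    return max(ridge_rel * float(lam_max), RIDGE_FLOOR)


def sym_power(S, spec: RegularizedPowerSpec) -> np.ndarray:
    """Regularized power of a symmetric PSD matrix via eigendecomposition.

    Returns ``V diag((clamp(λ, 0) + ridge)^q) Vᵀ`` for ``S = V diag(λ) Vᵀ``.
    ``S`` is symmetrized before decomposing; asymmetry beyond
    ``SYMMETRY_RTOL × max|S|`` is rejected.
    """
    S = _as_finite_2d(S, "S")
    if S.shape[0] != S.shape[1]:
        raise ValueError(f"S must be square, got shape {S.shape}")
    scale = np.abs(S).max() if S.size else 0.0
    asym = np.abs(S - S.T).max() if S.size else 0.0
    if asym > SYMMETRY_RTOL * max(scale, 1e-300):
        raise ValueError(
            f"S is not symmetric within tolerance (max asymmetry {asym:.3e})"
        )
    S = 0.5 * (S + S.T)
    lam, V = np.linalg.eigh(S)
    lam = np.clip(lam, 0.0, None) + spec.ridge
    return (V * lam**spec.exponent) @ V.T
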