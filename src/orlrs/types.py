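"""Core data containers for the ORLRS solver."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "SolverConfig",
    "IndicatorSet",
    "SolverState",
    "ClusteringResult",
    "SolverDivergedError",
]


class SolverDivergedError(RuntimeError):
    """Raised when an ALM iterate turns non-finite; carries the iteration index."""

    def __init__(self, message: str, iteration: int):
        super().__init__(f"{message} (outer iteration {iteration})")
        self.iteration = iteration


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with identifiers.

    Rows are genes/features, columns are samples — the orientation in which
    subspace clustering of samples operates on columns.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ValueError(f"need at least 1 gene and 2 samples, got {m}×{n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class IndicatorSet:
    """Discrete partition of n samples into c clusters.

    Equivalent to the c binary diagonal indicator matrices I_i with
    Σ_i I_i = I: every sample carries exactly one label in {0..c-1}.
    """

    labels: np.ndarray
    c: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.c < 1:
            raise ValueError(f"c must be >= 1, got {self.c}")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.c):
            raise ValueError(f"labels must lie in [0, {self.c})")

    @property
    def n(self) -> int:
        return self.labels.size

    def indicator_matrix(self) -> np.ndarray:
        """The c×n binary matrix C with C[i, j] = 1 iff sample j is in cluster i."""
        C = np.zeros((self.c, self.n), dtype=int)
        C[self.labels, np.arange(self.n)] = 1
        return C

    def members(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.labels == i)

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.c)


@dataclass
class SolverConfig:
    """All ORLRS hyperparameters, schedules, tolerances and seeds.

    The three model parameters are ``lam`` (balance λ between the low-rank and
    noise terms), ``theta`` (the capped-norm outlier threshold θ; +inf
    degrades the capped norm to L2,1), and ``k`` (the Schatten exponent,
    0 < k ≤ 1; k = 1 gives the Frobenius surrogate).  The rest drive the
    inexact-ALM schedule and stopping rules.
    """

    c: int
    lam: float = 1.0
    theta: float = math.inf
    k: float = 1.0
    mu0: float = 1e-2
    rho: float = 1.1
    mu_max: float = 1e8
    ridge: float = 1e-10
    max_outer: int = 200
    max_indicator_inner: int = 30
    tol_residual: float = 1e-7
    tol_objective: float = 1e-7
    restarts: int = 1
    seed: int = 0
    mode: str = "orlrs"

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError(f"c must be >= 2, got {self.c}")
        if not self.lam > 0:
            raise ValueError("lam must be > 0")
        if not self.theta > 0:
            raise ValueError("theta must be > 0")
        if not 0 < self.k <= 1:
            raise ValueError(f"k must be in (0, 1], got {self.k}")
        if not self.mu0 > 0:
            raise ValueError("mu0 must be > 0")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        if self.mu0 > self.mu_max:
            raise ValueError("mu0 must not exceed mu_max")
        if not self.ridge > 0:
            raise ValueError("ridge must be > 0")
        if self.tol_residual <= 0 or self.tol_objective <= 0:
            raise ValueError("tolerances must be > 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.mode not in ("orlrs", "lrs"):
            raise ValueError(f"mode must be 'orlrs' or 'lrs', got {self.mode!r}")

    def validate_against(self, X: ExpressionMatrix) -> None:
        if self.c > X.n_samples:
            raise ValueError(f"c={self.c} exceeds n={X.n_samples} samples")


@dataclass
class SolverState:
    """Mutable ALM state: primal blocks, multiplier, penalty, weights, traces."""

    A: np.ndarray
    E: np.ndarray
    Y: np.ndarray
    mu: float
    o_diag: np.ndarray
    indicators: IndicatorSet
    objective_history: list[float] = field(default_factory=list)
    residual_history: list[float] = field(default_factory=list)


@dataclass
class ClusteringResult:
    """Final labels plus the diagnostics a user needs to audit a run."""

    labels: np.ndarray
    objective_trace: list[float]
    outlier_flags: np.ndarray
    converged: bool
    n_outer: int
    final_residual: float
    # extra diagnostics (not part of the minimal contract, handy for audits)
    o_diag: np.ndarray | None = None
    e_column_norms: np.ndarray | None = None
    residual_trace: list[float] | None = None
    restart_objectives: list[float] | None = None
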