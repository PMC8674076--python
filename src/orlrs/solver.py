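"""The ORLRS solver.

One-step robust low-rank subspace segmentation: given an expression matrix
X (genes × samples) we seek a decomposition X = A + E where A is encouraged
to be low-rank *per cluster* through Schatten p-norm penalties on its
cluster-column blocks, E absorbs noise under a capped column norm that
writes off extreme-outlier samples, and a set of binary diagonal indicator
matrices I_i (equivalently a label vector) partitions the samples.  The
three blocks are updated in turn inside an inexact augmented-Lagrange loop
that enforces X = A + E; the labels fall out of the optimization directly,
with no affinity graph or spectral step.

The objective is

    min_{A,E,I}  Σ_i (‖A I_i‖_{S_p}^k)²  +  λ Σ_j min(‖E_j‖₂, θ)
    s.t.  X = A + E,   I_i binary diagonal,  Σ_i I_i = I

with the Schatten exponent convention p = 2k, under which the first term is
exactly Σ_i Tr((I_i Aᵀ A I_i)^k) = Σ_i Σ_l σ_l(A I_i)^{2k}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve as _sym_solve

from .norms import (
    RegularizedPowerSpec,
    capped_norm,
    column_norms,
    effective_ridge,
    low_rank_term,
    sym_power,
)
from .types import (
    ClusteringResult,
    ExpressionMatrix,
    IndicatorSet,
    SolverConfig,
    SolverDivergedError,
)

__all__ = [
    "objective",
    "update_A",
    "update_weights",
    "update_E",
    "cluster_scores",
    "assign_labels",
    "update_indicators",
    "fit",
    "fit_lrs",
    "BlockRecord",
    "augmented_merit",
]

#: norm floor used inside the IRLS weight 1/(2‖E_j‖₂) for zero-residual columns
EPS_NORM = 1e-10


# ---------------------------------------------------------------------------
# objective and block updates
# ---------------------------------------------------------------------------

def _partition_term(A: np.ndarray, labels: np.ndarray, c: int, k: float) -> float:
    """Σ_i Tr((A_iᵀ A_i)^k) over the cluster column blocks of A."""
    return sum(low_rank_term(A[:, labels == i], k) for i in range(c))


def objective(X: ExpressionMatrix, A, E, ind: IndicatorSet, cfg: SolverConfig) -> float:
    """Value of the ORLRS objective at (A, E, labels).

    Σ_i low-rank term of the columns labelled i, plus λ × capped norm of E.
    Zero-padded cluster blocks and plain column submatrices have identical
    singular values, so the submatrix route is exact.
    """
    A = np.asarray(A, dtype=float)
    E = np.asarray(E, dtype=float)
    if A.shape != X.values.shape or E.shape != X.values.shape:
        raise ValueError("A and E must match the shape of X")
    if ind.n != X.n_samples:
        raise ValueError("indicator length must equal the number of samples")
    if ind.c != cfg.c:
        raise ValueError("indicator cluster count disagrees with config")
    return _partition_term(A, ind.labels, ind.c, cfg.k) + cfg.lam * capped_norm(
        E, cfg.theta
    )


def update_A(X, E, Y, mu: float, A_prev, k: float, ridge: float) -> np.ndarray:
    """Closed-form A block update.

    With B = X − E + Y/μ and the IRLS curvature H = k (A_prevᵀ A_prev)^{k−1}
    (ridge-regularized), the stationarity condition 2AH + μ(A − B) = 0 gives
    A = μ B (2H + μI)⁻¹.  For k = 1, H = I and the update is the pure
    shrinkage (μ/(2+μ)) B.
    """
    X = np.asarray(X, float)
    E = np.asarray(E, float)
    Y = np.asarray(Y, float)
    A_prev = np.asarray(A_prev, float)
    if not mu > 0:
        raise ValueError("mu must be > 0")
    if not 0 < k <= 1:
        raise ValueError(f"k must be in (0, 1], got {k}")
    for name, M in (("X", X), ("E", E), ("Y", Y), ("A_prev", A_prev)):
        if not np.all(np.isfinite(M)):
            raise ValueError(f"{name} contains non-finite entries")
    B = X - E + Y / mu
    n = A_prev.shape[1]
    G = A_prev.T @ A_prev
    lam_max = float(np.linalg.eigvalsh(G)[-1]) if n else 0.0
    eps = effective_ridge(lam_max, ridge)
    H = k * sym_power(G, RegularizedPowerSpec(k - 1.0, eps))
    M = 2.0 * H + mu * np.eye(n)
    # M is SPD (H PSD, mu > 0); A solves A M = mu B
    return mu * _sym_solve(M, B.T, assume_a="pos").T


def update_weights(E, theta: float) -> np.ndarray:
    """IRLS weights o_j for the capped-norm noise term.

    o_j = 1/(2‖E_j‖₂) while the column residual stays strictly below θ, and 0
    once it reaches θ — flagged outlier columns drop out of the quadratic
    noise penalty entirely.  Zero-residual columns get the capped weight
    1/(2·EPS_NORM).
    """
    if not theta > 0:
        raise ValueError("theta must be > 0")
    norms = column_norms(E)
    return np.where(norms < theta, 1.0 / (2.0 * np.maximum(norms, EPS_NORM)), 0.0)


def update_E(X, A, Y, mu: float, lam: float, o_diag) -> np.ndarray:
    """Closed-form E block update given fixed IRLS weights.

    With F = X − A + Y/μ, the diagonal weight matrix makes the stationarity
    condition 2λEO + μ(E − F) = 0 separable per column:
    E_j = (μ / (2λ o_j + μ)) F_j.
    """
    if not mu > 0 or not lam > 0:
        raise ValueError("mu and lam must be > 0")
    o_diag = np.asarray(o_diag, dtype=float)
    if np.any(o_diag < 0):
        raise ValueError("weights must be nonnegative")
    F = np.asarray(X, float) - np.asarray(A, float) + np.asarray(Y, float) / mu
    scale = mu / (2.0 * lam * o_diag + mu)
    return F * scale[np.newaxis, :]


# ---------------------------------------------------------------------------
# indicator (label) update
# ---------------------------------------------------------------------------

def cluster_scores(A, ind: IndicatorSet, k: float, ridge: float) -> np.ndarray:
    """Per-sample, per-cluster assignment costs z[j, i].

    For each cluster i with column block A_i, z[:, i] is the diagonal of
    Zᵢ = Aᵀ Lᵢ A where Lᵢ = k‖A_i‖_{S_p}^k (A_i A_iᵀ)^{(k−2)/2} (ridge-
    regularized).  The m×m fractional power is never formed densely: from the
    thin SVD A_i = U diag(s) Vᵀ,

        (A_i A_iᵀ + εI)^q = ε^q I + U diag((s²+ε)^q − ε^q) Uᵀ,

    which matches the dense eigendecomposition exactly (the ε-ridge defines
    the null-space contribution).  Columns of empty clusters are set to +inf
    so an empty cluster is never chosen before it is explicitly reseeded.
    """
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("A contains non-finite entries")
    n = A.shape[1]
    if ind.n != n:
        raise ValueError("indicator length must equal the number of columns of A")
    counts = ind.counts()
    if not counts.any():
        raise ValueError("all clusters are empty")
    q = (k - 2.0) / 2.0
    col_sq = np.einsum("ij,ij->j", A, A)
    scores = np.full((n, ind.c), np.inf)
    for i in range(ind.c):
        if counts[i] == 0:
            continue
        Ai = A[:, ind.labels == i]
        U, s, _ = np.linalg.svd(Ai, full_matrices=False)
        s2k = np.sum(s ** (2.0 * k))
        s_i = k * np.sqrt(s2k)
        if s_i == 0.0:  # zero block: L_i vanishes with its prefactor
            scores[:, i] = 0.0
            continue
        eps = effective_ridge(float(s[0] ** 2), ridge)
        epsq = eps**q
        coef = (s**2 + eps) ** q - epsq
        P = U.T @ A
        scores[:, i] = s_i * (epsq * col_sq + coef @ (P**2))
    return scores


def assign_labels(scores) -> IndicatorSet:
    """Argmin assignment over clusters, ties broken by lowest cluster index.

    The indicator subproblem is separable per sample, so the row-wise argmin
    attains its global optimum for fixed scores.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(np.isnan(scores)):
        raise ValueError("scores contain NaN")
    return IndicatorSet(labels=np.argmin(scores, axis=1), c=scores.shape[1])


def _reseed_empty(labels: np.ndarray, scores: np.ndarray, c: int) -> np.ndarray:
    """Move the worst-fitting sample into each empty cluster.

    An empty cluster would make its score column degenerate, so each one is
    reseeded with the sample whose own-cluster cost is largest, among samples
    whose current cluster keeps at least two members.
    """
    labels = labels.copy()
    counts = np.bincount(labels, minlength=c)
    for i in np.flatnonzero(counts == 0):
        own = scores[np.arange(labels.size), labels]
        movable = counts[labels] >= 2
        if not movable.any():
            break
        j = int(np.flatnonzero(movable)[np.argmax(own[movable])])
        counts[labels[j]] -= 1
        labels[j] = i
        counts[i] += 1
    return labels


def _seed_empty_by_norm(A: np.ndarray, labels: np.ndarray, c: int) -> np.ndarray:
    """Fill empty clusters in an *input* partition (no scores available yet)."""
    labels = labels.copy()
    counts = np.bincount(labels, minlength=c)
    norms = column_norms(A)
    for i in np.flatnonzero(counts == 0):
        movable = counts[labels] >= 2
        if not movable.any():
            break
        j = int(np.flatnonzero(movable)[np.argmax(norms[movable])])
        counts[labels[j]] -= 1
        labels[j] = i
        counts[i] += 1
    return labels


def update_indicators(
    A, ind: IndicatorSet, k: float, ridge: float, max_inner: int
) -> IndicatorSet:
    """Alternate cluster_scores / assign_labels until the labels fix-point.

    For k = 1 the partition term Σ_i ‖A I_i‖_F² is partition-invariant, so
    every pass trivially preserves the objective; for k < 1 descent of the
    partition term is monitored and the loop keeps the best labels seen,
    stopping if the tracked value rises.
    """
    A = np.asarray(A, dtype=float)
    labels = ind.labels.copy()
    c = ind.c
    if max_inner <= 0:
        return IndicatorSet(labels=labels, c=c)
    labels = _seed_empty_by_norm(A, labels, c)
    track = k < 1.0
    best = labels.copy()
    best_J = _partition_term(A, labels, c, k) if track else 0.0
    seen = {labels.tobytes()}
    for _ in range(max_inner):
        scores = cluster_scores(A, IndicatorSet(labels=labels, c=c), k, ridge)
        new = np.argmin(scores, axis=1)
        new = _reseed_empty(new, scores, c)
        if np.array_equal(new, labels):
            break
        if track:
            J = _partition_term(A, new, c, k)
            if J > best_J * (1.0 + 1e-12) + 1e-300:
                labels = best
                break
            if J < best_J:
                best_J, best = J, new.copy()
        labels = new
        key = labels.tobytes()
        if key in seen:  # oscillation between equally-scored partitions
            break
        seen.add(key)
    return IndicatorSet(labels=labels, c=c)


# ---------------------------------------------------------------------------
# outer ALM loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockRecord:
    """Objective/merit snapshot taken right after one block update."""

    outer: int
    block: str  # "init", "A", "E" or "I"
    objective: float
    merit: float
    mu: float


def augmented_merit(
    X, A, E, labels, c: int, k: float, lam: float, theta: float, Y, mu: float
) -> float:
    """Augmented-Lagrangian merit: objective + (μ/2)‖A + E − X − Y/μ‖²_F.

    Each block update provably does not increase this quantity at fixed
    (Y, μ): the A and E solves minimize their IRLS majorizers of it, and the
    label update leaves the penalty untouched.
    """
    R = A + E - X - Y / mu
    return (
        _partition_term(A, labels, c, k)
        + lam * capped_norm(E, theta)
        + 0.5 * mu * float(np.sum(R * R))
    )


def _check_finite(M: np.ndarray, it: int, name: str) -> None:
    if not np.all(np.isfinite(M)):
        raise SolverDivergedError(f"{name} became non-finite", it)


def _fit_single(
    Xv: np.ndarray,
    cfg: SolverConfig,
    init: IndicatorSet,
    block_records: list[BlockRecord] | None = None,
) -> ClusteringResult:
    m, n = Xv.shape
    A = Xv.copy()
    E = np.zeros_like(Xv)
    Y = np.zeros_like(Xv)
    mu = cfg.mu0
    labels = init.labels.copy()
    x_norm = max(float(np.linalg.norm(Xv)), 1e-300)

    def _obj(Acur, Ecur, lab) -> float:
        return _partition_term(Acur, lab, cfg.c, cfg.k) + cfg.lam * capped_norm(
            Ecur, cfg.theta
        )

    def _record(outer: int, block: str, Acur, Ecur, lab) -> None:
        if block_records is None:
            return
        block_records.append(
            BlockRecord(
                outer=outer,
                block=block,
                objective=_obj(Acur, Ecur, lab),
                merit=augmented_merit(
                    Xv, Acur, Ecur, lab, cfg.c, cfg.k, cfg.lam, cfg.theta, Y, mu
                ),
                mu=mu,
            )
        )

    obj_trace = [_obj(A, E, labels)]
    res_trace = [0.0]  # A + E = X holds exactly at the feasible start
    converged = False
    n_outer = 0

    for it in range(1, cfg.max_outer + 1):
        n_outer = it
        _record(it, "init", A, E, labels)

        A = update_A(Xv, E, Y, mu, A, cfg.k, cfg.ridge)
        _check_finite(A, it, "A")
        _record(it, "A", A, E, labels)

        o_diag = update_weights(E, cfg.theta)
        E = update_E(Xv, A, Y, mu, cfg.lam, o_diag)
        _check_finite(E, it, "E")
        _record(it, "E", A, E, labels)

        ind = update_indicators(
            A,
            IndicatorSet(labels=labels, c=cfg.c),
            cfg.k,
            cfg.ridge,
            cfg.max_indicator_inner,
        )
        labels = ind.labels
        _record(it, "I", A, E, labels)

        # multiplier ascent consistent with B = X−E+Y/μ and F = X−A+Y/μ:
        # the Lagrangian penalty is (μ/2)‖A+E−X−Y/μ‖², so Y ← Y − μ(A+E−X)
        R = A + E - Xv
        Y = Y - mu * R
        mu = min(cfg.rho * mu, cfg.mu_max)

        obj = _obj(A, E, labels)
        residual = float(np.linalg.norm(R)) / x_norm
        obj_trace.append(obj)
        res_trace.append(residual)

        rel_change = abs(obj - obj_trace[-2]) / max(abs(obj_trace[-2]), 1e-300)
        if residual < cfg.tol_residual and rel_change < cfg.tol_objective:
            converged = True
            break

    e_norms = column_norms(E)
    return ClusteringResult(
        labels=labels,
        objective_trace=obj_trace,
        outlier_flags=e_norms >= cfg.theta,
        converged=converged,
        n_outer=n_outer,
        final_residual=res_trace[-1],
        o_diag=update_weights(E, cfg.theta),
        e_column_norms=e_norms,
        residual_trace=res_trace,
    )


def fit(
    X: ExpressionMatrix,
    cfg: SolverConfig,
    init_labels: IndicatorSet | None = None,
    block_records: list[BlockRecord] | None = None,
) -> ClusteringResult:
    """Run the full ORLRS solver on an expression matrix.

    Initialization: A = X, E = 0, Y = 0, μ = μ₀ (a feasible start), labels
    from ``init_labels`` or a seeded K-means on the sample columns.  Each
    outer iteration performs the A solve, one IRLS weight pass + E solve, the
    indicator loop, then the multiplier and penalty updates Y ← Y + μ(A+E−X),
    μ ← min(ρμ, μ_max).  With ``cfg.restarts > 1`` the solver reruns from
    distinct K-means seeds (cfg.seed, cfg.seed+1, …) and returns the run with
    the lowest final objective.
    """
    from .io import kmeans_init  # local import: io also imports types

    cfg.validate_against(X)
    best: ClusteringResult | None = None
    restart_objs: list[float] = []
    for t in range(cfg.restarts):
        if t == 0 and init_labels is not None:
            init = init_labels
        else:
            init = kmeans_init(X, cfg.c, seed=cfg.seed + t)
        if init.n != X.n_samples or init.c != cfg.c:
            raise ValueError("init_labels does not match X / cfg.c")
        res = _fit_single(
            X.values, cfg, init, block_records if t == 0 else None
        )
        restart_objs.append(res.objective_trace[-1])
        if best is None or res.objective_trace[-1] < best.objective_trace[-1]:
            best = res
    assert best is not None
    best.restart_objectives = restart_objs
    return best


def fit_lrs(
    X: ExpressionMatrix,
    cfg: SolverConfig,
    init_labels: IndicatorSet | None = None,
) -> ClusteringResult:
    """Noiseless one-step baseline: indicator optimization directly on X.

    No noise matrix and no ALM — A := X and the label loop runs to a fixed
    point.  The trace records the noiseless objective Σ_i (‖X I_i‖_{S_p}^k)²
    after every pass.
    """
    from .io import kmeans_init

    cfg.validate_against(X)
    Xv = X.values
    best: ClusteringResult | None = None
    restart_objs: list[float] = []
    for t in range(cfg.restarts):
        if t == 0 and init_labels is not None:
            labels = init_labels.labels.copy()
        else:
            labels = kmeans_init(X, cfg.c, seed=cfg.seed + t).labels
        labels = _seed_empty_by_norm(Xv, labels, cfg.c)
        trace = [_partition_term(Xv, labels, cfg.c, cfg.k)]
        converged = False
        n_pass = 0
        for n_pass in range(1, cfg.max_outer + 1):
            new = update_indicators(
                Xv, IndicatorSet(labels=labels, c=cfg.c), cfg.k, cfg.ridge, 1
            ).labels
            if np.array_equal(new, labels):
                converged = True
                break
            J = _partition_term(Xv, new, cfg.c, cfg.k)
            if cfg.k < 1.0 and J > trace[-1] * (1.0 + 1e-12):
                converged = True  # descent guard: keep current labels
                break
            labels = new
            trace.append(J)
        res = ClusteringResult(
            labels=labels,
            objective_trace=trace,
            outlier_flags=np.zeros(X.n_samples, dtype=bool),
            converged=converged,
            n_outer=n_pass,
            final_residual=0.0,
        )
        restart_objs.append(trace[-1])
        if best is None or res.objective_trace[-1] < best.objective_trace[-1]:
            best = res
    assert best is not None
    best.restart_objectives = restart_objs
    return best
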