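# Methods

## Model

ORLRS (one-step robust low-rank subspace segmentation) assumes the n sample
columns of an expression matrix `X ∈ ℝ^{m×n}` lie near a union of `c`
low-dimensional linear subspaces, contaminated by dense noise and by a small
number of extreme-outlier samples. It fits

```
min_{A,E,I}  Σ_i (‖A I_i‖_{S_p}^k)²  +  λ Σ_j min(‖E_j‖₂, θ),   X = A + E,
```

where the `I_i` are binary diagonal indicator matrices partitioning the
samples (`Σ_i I_i = I`), `‖·‖_{S_p}` is the Schatten p-norm, and the capped
column norm on `E` charges a flat cost θ to any sample whose residual norm
reaches θ.

**Schatten exponent convention.** The low-rank term is written
`(‖G‖_{S_p}^k)²` with `p` unspecified in the usual presentation; this package
fixes `p = 2k`, the unique choice under which
`(‖G‖_{S_p}^k)² = Tr((GᵀG)^k) = Σ_l σ_l(G)^{2k}` holds exactly, making the
trace identity used by the A-step and the derivative formulas of the
indicator step algebraically exact rather than inequalities. `k = 1` gives
the squared Frobenius norm; `0 < k < 1` tightens the rank surrogate.

A consequence worth stating plainly: **at `k = 1` the low-rank term is
partition-invariant** (`Σ_i ‖A I_i‖_F² = ‖A‖_F²` for every partition), so the
objective value carries no clustering information; the labels are determined
entirely by the fixed-point structure of the indicator update below. For
`k < 1` the objective genuinely prefers subspace-pure blocks.

## Optimization

The equality constraint is handled by inexact ALM with multiplier `Y` and
penalty `μ`, minimizing blocks of
`Σ_i Tr((I_i Aᵀ A I_i)^k) + λ·capped(E, θ) + (μ/2)‖A + E − X − Y/μ‖²_F`.

* **A step.** With `B = X − E + Y/μ` and the IRLS curvature
  `H = k (A_prevᵀ A_prev)^{k−1}` (held fixed at the previous iterate), the
  stationarity condition `2AH + μ(A − B) = 0` gives the closed form
  `A = μ B (2H + μI)⁻¹`. At `k = 1`, `H = I` and the update is the pure
  shrinkage `(μ/(2+μ)) B`. Fractional powers use the eigendecomposition with
  eigenvalues clamped at zero and ridged (below).
* **E step.** One IRLS pass on the capped norm: weights
  `o_j = 1/(2‖E_j‖₂)` if `‖E_j‖₂ < θ` (strict; zero at and above the
  threshold), then with `F = X − A + Y/μ` the weighted quadratic has the
  per-column solution `E_j = (μ/(2λ o_j + μ)) F_j`. A column flagged as
  outlier (`o_j = 0`) passes `F_j` through unchanged — it is absorbed
  entirely by the noise matrix at flat cost θ. Zero-residual columns take
  the capped weight `1/(2·10⁻¹⁰)` so the weight stays finite.
* **Indicator step.** For each cluster,
  `L_i = k‖A I_i‖_{S_p}^k (A I_i Aᵀ)^{(k−2)/2}` and the per-sample cost for
  cluster i is `z_{j,i} = (Aᵀ L_i A)_{jj}`; each sample moves to its argmin
  cluster (ties to the lowest index), and scores/assignment alternate until
  the labels fix-point or an iteration cap. The m×m fractional power is
  computed from the thin SVD of the cluster block
  (`(A_iA_iᵀ + εI)^q = ε^q I + U diag((s²+ε)^q − ε^q) Uᵀ`), which matches the
  dense eigendecomposition exactly while costing O(m·n_i²).
* **Multiplier / penalty.** `Y ← Y − μ(A + E − X)`, `μ ← min(ρμ, μ_max)`.
  The sign follows from the `B`/`F` definitions above (the penalty is
  `(μ/2)‖A+E−X−Y/μ‖²`); with the opposite sign the dual iterate doubles each
  step and the ALM diverges.

Initialization is the feasible point `A = X, E = 0, Y = 0`, with labels from
seeded K-means (k-means++ start, single initialization per seed) on the
sample columns. The loop stops when the scaled residual `‖A+E−X‖_F/‖X‖_F`
falls below `tol_residual` and the relative objective change below
`tol_objective`, or at `max_outer`. With `restarts > 1` the solver reruns
from consecutive K-means seeds and keeps the lowest final objective (note
this selection is uninformative at `k = 1`, where the objective is
partition-invariant).

`fit_lrs` is the noiseless one-step baseline: the indicator loop applied
directly to X (no `E`, no ALM), tracking `Σ_i (‖X I_i‖_{S_p}^k)²`.

## What provably decreases, and what does not

Each block update does not increase the **augmented-Lagrangian merit** above
at fixed `(Y, μ)`: the A step minimizes it exactly at `k = 1` and via a
linearized majorizer for `k < 1`; the E step is a
majorize–minimize step on the capped norm (the weighted quadratic majorizes
`min(‖E_j‖, θ)` at the current iterate, up to the 10⁻¹⁰ weight floor); the
label step changes only the low-rank term, which it cannot increase at
`k = 1` (invariance) and is guarded for `k < 1` (the inner loop keeps the
best labels seen and aborts on an increase). The regular test suite asserts
this merit descent (observed worst per-block relative increase ≤ 3e-11).

The **raw objective**, by contrast, is *not* monotone across individual
block updates along the ALM trajectory, and cannot be: starting from the
feasible point `E = 0`, the capped term must grow from 0 to its stationary
value, so E updates strictly increase it; and under a growing penalty the
low-rank term first collapses (`A = (μ/(2+μ))B` with small μ₀) and then
regrows. Only the merit, not the raw objective, is the correct per-block
Lyapunov function for this scheme.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `c` | number of clusters | required | ≤ n |
| `lam` (λ) | noise/low-rank balance | 1.0 | useful range ≈ 0.1–2 |
| `theta` (θ) | capped-norm outlier threshold | +∞ | data-scale dependent; no universal default is defensible — set explicitly or via a column-norm quantile; +∞ = L2,1 |
| `k` | Schatten exponent, (0, 1] | 1.0 | < 1 tightens the rank surrogate |
| `mu0`, `rho`, `mu_max` | ALM penalty schedule | 1e-2, 1.1, 1e8 | residual < 1e-6 within ~100 outer iterations on the study fixtures |
| `ridge` (ε) | relative eigenvalue ridge for fractional powers | 1e-10 | ε_abs = ridge × largest eigenvalue, floored at 1e-12 |
| `max_outer`, `max_indicator_inner` | iteration caps | 200, 30 | |
| `tol_residual`, `tol_objective` | stopping tolerances | 1e-7, 1e-7 | |
| `restarts`, `seed` | K-means restart protocol | 1, 0 | |

Empty clusters after an assignment pass are reseeded with the sample whose
own-cluster cost is largest (among samples whose cluster keeps ≥ 2 members),
then scoring resumes — the model needs c nonempty blocks for `L_i` to be
meaningful.

## Synthetic data

The generator draws, per cluster, an orthonormal basis `U_i` (mutually
orthogonal across clusters when requested and `Σ r_i ≤ m`), standard-normal
coefficients, i.i.d. Gaussian noise of sd σ, and replaces a fixed fraction
of columns with uniformly-directed outliers whose norm is pegged to
`outlier_scale ×` the median clean column norm — guaranteeing they sit past
any sensible θ. Defaults model the study conditions used throughout the
tests: m = 60, three 3-dimensional orthogonal subspaces with 15 samples
each; the noisy variant adds σ = 0.05 and 10 % outliers at 10× scale. The
canonical noiseless instance (`clean_recovery_case`) is the recovery
benchmark.

The generator deliberately does **not** emulate expression-platform realism
(nonnegativity, counts, mean–variance coupling, batch structure): it
realizes exactly the model the algorithm assumes, so passing tests certify
the optimization and robustness machinery, not performance on real tumor
data.

## Known limitations

* **Initialization sensitivity.** Subspace clusters pass through the origin,
  so their columns form overlapping, zero-mean clouds that K-means cannot
  separate (measured mean init ACC ≈ 0.52 on the canonical fixture, never
  exact). The indicator map reliably repairs initializations within roughly
  20 % label corruption, but from raw K-means it reaches the exact partition
  on only about half the seeds (ORLRS) and rarely for the noiseless baseline.
* **Merge/split fixed points.** At `k = 1` a configuration where one
  subspace is split across two clusters and two subspaces share one cluster
  is a stable fixed point of the batch score/assign map, and costs nothing
  in the (partition-invariant) objective.
* **Noise freezes the map.** With dense noise each sample column carries a
  private noise direction that only its own cluster block can represent; at
  the default ridge the off-span penalty `ε^{(k−2)/2}` then dominates every
  score and the label map barely moves from its initialization (it still
  preserves a correct labelling perfectly). Clustering quality on noisy data
  is therefore governed largely by the initialization — while outlier
  identification, which runs through `E` and the IRLS weights, is
  essentially initialization-independent and exact on the study fixtures.
* **θ selection.** The capped threshold is data-scale dependent; the CLI's
  quantile rule is a pragmatic default, not a calibrated estimator.

## Problem sizes

All tests and the acceptance script run on 60×45 instances (three clusters
of 15) with up to 100 seeds/instances per property; the full suite completes
in well under a minute of compute plus the 100-seed recovery and descent
scans (~half a minute each) on one CPU.
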