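# orlrs — one-step robust low-rank subspace segmentation

`orlrs` clusters the samples of a gene-expression matrix (bulk microarray /
RNA-seq style, genes × samples) under the assumption that samples drawn from
the same tumor type lie near a common low-dimensional linear subspace, so the
whole data set lives near a *union of subspaces*. Unlike classical low-rank
representation pipelines, which first build an affinity graph and then run
spectral clustering, ORLRS optimizes discrete cluster indicators *inside* the
matrix decomposition and returns labels in one step. It is aimed at
computational biologists who want a subspace-structured alternative to
K-means / NMF-style tumor sample clustering, and at methods researchers who
want a reference implementation of capped-norm-robust low-rank segmentation.

## Model

Given `X ∈ ℝ^{m×n}` (m genes, n samples) and a cluster count `c`, the method
seeks a decomposition `X = A + E` together with binary diagonal indicator
matrices `I_1, …, I_c` (`Σ_i I_i = I`, one cluster per sample) minimizing

```
min_{A,E,I}   Σ_{i=1}^{c} (‖A I_i‖_{S_p}^k)²  +  λ Σ_{j=1}^{n} min(‖E_j‖₂, θ)
s.t.          X = A + E
```

* **Low-rank term** — `‖·‖_{S_p}` is the Schatten p-norm over singular
  values; with the convention `p = 2k` the cluster term equals
  `Tr((I_i AᵀA I_i)^k) = Σ_l σ_l(A I_i)^{2k}`, a tight rank surrogate for
  `0 < k < 1` and the squared Frobenius norm at `k = 1`.
* **Capped noise norm** — each sample column of the noise matrix pays
  `min(‖E_j‖₂, θ)`: columns whose residual exceeds the threshold θ are
  written off at a flat cost, so extreme outlier samples stop influencing
  the fit entirely (θ = ∞ recovers the L2,1 norm).
* **One-step labels** — the indicators are optimized directly by alternating
  a per-sample score matrix `z_{j,i} = diag(Aᵀ L_i A)_j`, with
  `L_i = k‖A I_i‖_{S_p}^k (A I_i Aᵀ)^{(k−2)/2}`, and an argmin assignment.

The equality constraint is enforced by an inexact augmented-Lagrange loop
(multiplier `Y`, growing penalty `μ`), with closed-form `A` and `E` block
updates (the `E` step is one IRLS pass on the capped norm). See
`docs/methods.md` for the update formulas, schedules and numerical choices.

## Worked example

```python
import numpy as np
from orlrs import fit, SolverConfig, clean_recovery_case
from orlrs.evaluation import LabelPair, clustering_accuracy, nmi

X, truth = clean_recovery_case(seed=7)   # 3 orthogonal 3-dim subspaces, 60×45
res = fit(X, SolverConfig(c=3, k=1.0, theta=np.inf, seed=2))
pair = LabelPair(truth.labels, res.labels)
print(f"converged: {res.converged} after {res.n_outer} iterations")
print(f"final residual = {res.final_residual:.2e}")
print(f"ACC = {clustering_accuracy(pair):.4f}   NMI = {nmi(pair):.4f}")
```

prints

```
converged: True after 168 iterations
final residual = 6.26e-11
ACC = 1.0000   NMI = 1.0000
```

ACC is the best-mapping clustering accuracy, NMI the normalized mutual
information against the generator's ground truth; the residual is
`‖A+E−X‖_F/‖X‖_F`, i.e. how tightly the ALM closed the constraint. The
labels depend on the seeded K-means initialization: on this fixture roughly
half of the initializations reach the exact partition (the others land in
stable merge/split configurations; see `docs/methods.md`), so multiple
seeds/restarts are recommended in practice.

Outlier identification is much less initialization-sensitive. On a noisy
instance (σ = 0.05) with 10 % extreme-outlier columns at 10× the median
column norm and θ = 8 chosen between the clean (≤ 4.2) and outlier (≥ 15.3)
column-norm scales:

```python
from orlrs.synthetic import SubspaceSpec, generate
spec = SubspaceSpec(ambient_dim=60, samples_per_cluster=[15, 15, 15],
                    subspace_dims=[3, 3, 3], noise_sd=0.05,
                    outlier_fraction=0.10, outlier_scale=10.0, seed=3)
Xn, tn, mask = generate(spec)
res = fit(Xn, SolverConfig(c=3, theta=8.0, seed=0))
print((res.outlier_flags == mask).all(), int(res.outlier_flags.sum()))
```

prints `True 4`: all four injected outliers are flagged (their IRLS weights
are exactly zero) and no clean column is.

## Command line

```bash
orlrs simulate --output X.tsv --truth-output truth.tsv --noise-sd 0.05 \
      --outlier-fraction 0.1 --seed 3
orlrs fit --input X.tsv --clusters 3 --theta 8 --seed 0 --output labels.tsv
orlrs eval --pred labels.tsv --truth truth.tsv
```

`fit` writes a two-column labels TSV plus a diagnostics JSON (objective and
residual traces, outlier flags, config echo). θ has no universal default —
pass `--theta`, or `--theta-quantile q` to set it from the column-norm
distribution; `--theta inf` gives the uncapped L2,1 behaviour. `--mode lrs`
runs the noiseless one-step baseline (indicator optimization directly on X,
no noise matrix).

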