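# unico

Covariance-aware deconvolution of bulk genomic profiles into sample-specific
cell-type-level signals.

Bulk transcriptomic or DNA-methylation measurements from heterogeneous
tissue mix the contributions of many cell types. Given a bulk matrix
(samples x features, linear scale) and per-sample cell-type proportions
(from any reference-based decomposition tool), this package estimates, for
every feature *j*:

* the mean cell-type levels `mu_j` (length k, nonnegative),
* the full k x k cell-type covariance `Sigma_j`,
* the technical-noise variance `tau_j^2`,

under the model `X_ij = w_i' Z_ij + e_ij`, `Z_ij = mu_j + eps_ij` with
`Var[eps_ij] = Sigma_j`, `Var[e_ij] = tau_j^2`, and then reconstructs the
samples x features x cell-types tensor with the closed-form conditional
estimator

    zhat_ij = E[Z|theta_j] + Sigma_j w_i (x_ij - w_i'mu_j) / (w_i'Sigma_j w_i + tau_j^2).

Modeling the cell-type covariance is the point: the bulk residual is pushed
back to cell types along `Sigma_j w_i`, so features with strong cross-cell-
type correlation (low von Neumann entropy) deconvolve far better than any
estimator that ignores covariance. Parameters are fitted by distribution-free,
iteratively re-weighted moment matching (a GMM-style weighted least-squares
scheme with nonnegative means, an L2-penalized covariance solve and 2-SD
outlier masking). The package is modality-agnostic — the same machinery
applies to CPM-normalized expression and beta-normalized methylation.

Also included: one-step cell-type-level association tests (parametric and
distribution-free sandwich variants, marginal per cell type and joint
tissue-level), a discovery/validation replication scorer (MCC/F1 with
Bonferroni rules), evaluation statistics (robust trimmed correlation,
normalized von Neumann entropy, root-median-square error, the
delta-log10(p) information-beyond-bulk score, moment-recovery scoring,
effect-beyond-composition regression), and two synthetic-data generators
(fully parametric, and resampling pseudo-bulk from profile pools).
See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import numpy as np
import unico
from unico.core import baseline_tensor, estimate_tensor
from unico.evaluation import moment_recovery, robust_correlation

truth = unico.simulate_parametric(n=500, m=200, k=3, seed=1)
fit = unico.fit(truth.bulk, truth.proportions)

rec = moment_recovery(truth.tensor, fit)
print("mean recovery per cell type:", np.round(rec.mean_correlation, 3))

z = estimate_tensor(truth.bulk, truth.proportions, fit)
zb = baseline_tensor(truth.bulk, truth.proportions)
rs = [robust_correlation(truth.tensor.values[:, j, h], z.values[:, j, h])
      for j in range(0, 200, 4) for h in range(3)]
rb = [robust_correlation(truth.tensor.values[:, j, h], zb.values[:, j, h])
      for j in range(0, 200, 4) for h in range(3)]
print("median tensor-truth correlation:", round(float(np.median(rs)), 3))
print("median baseline-truth correlation:", round(float(np.median(rb)), 3))
```

prints

```
mean recovery per cell type: [0.998 0.995 0.991]
median tensor-truth correlation: 0.562
median baseline-truth correlation: 0.162
```

The fitted mean cell-type levels correlate with the generating truth at
0.99+ per cell type across 200 features, and the per-feature, per-cell-type
correlation between the deconvolved tensor and the true hidden levels
(median 0.56 here, higher for low-entropy features) far exceeds the naive
baseline `z_ijh = x_ij * w_ih` (0.16), which mostly reflects proportions
rather than sample-specific biology.

The same pipeline runs from the shell:

```sh
unico simulate --n 500 --m 200 --k 3 --seed 1 --out sim/
unico fit --bulk sim/bulk.tsv --proportions sim/proportions.tsv --out fit.npz
unico tensor --bulk sim/bulk.tsv --proportions sim/proportions.tsv \
      --fit fit.npz --out tensor.npz
unico evaluate --truth sim/tensor.npz --estimate tensor.npz --out eval.tsv
```

with `unico assoc` and `unico replicate` for phenotype testing and
cross-cohort replication scoring.

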