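"""Independent reference implementations used only to check the package."""
from __future__ import annotations

import numpy as np


def gaussian_conditional(mu, sigma, tau2, w, x):
    """Textbook joint-Gaussian conditioning for (Z, X = w'Z + e).

    Builds the full (k+1)-dimensional joint covariance and applies the
    generic block formulas m1 + C12 C22^-1 (x - m2) and
    C11 - C12 C22^-1 C21; shares no code with the estimator under test.
    """
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    w = np.asarray(w, float)
    k = mu.shape[0]
    joint_mean = np.concatenate([mu, [w @ mu]])
    joint_cov = np.empty((k + 1, k + 1))
    joint_cov[:k, :k] = sigma
    joint_cov[:k, k] = sigma @ w
    joint_cov[k, :k] = sigma @ w
    joint_cov[k, k] = w @ sigma @ w + tau2
    c22 = joint_cov[k, k]
    cond_mean = joint_mean[:k] + joint_cov[:k, k] * (x - joint_mean[k]) / c22
    cond_cov = joint_cov[:k, :k] - np.outer(
        joint_cov[:k, k], joint_cov[k, :k]
    ) / c22
    return cond_mean, cond_cov


def replication_counts(p_d, p_v, e_d, e_v, alpha=0.05):
    """Brute-force discovery/validation confusion counts by explicit set ops."""
    m = len(p_d)
    hits = {j for j in range(m) if p_d[j] <= alpha / m}
    thr_v = alpha / max(len(hits), 1)
    tp_set = set()
    for j in hits:
        direction_ok = True
        if e_d is not None:
            direction_ok = np.sign(e_d[j]) == np.sign(e_v[j])
        if p_v[j] <= thr_v and direction_ok:
            tp_set.add(j)
    fn_set = hits - tp_set
    controls = {j for j in range(m) if p_d[j] > 0.95}
    thr_c = alpha / max(len(controls), 1)
    fp_set = {j for j in controls if p_v[j] <= thr_c}
    tn_set = controls - fp_set
    return len(tp_set), len(fp_set), len(tn_set), len(fn_set)


def mcc_formula(tp, fp, tn, fn):
    denom = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom
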