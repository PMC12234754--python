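"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's own code paths: the ALS oracle
builds the dense penalty matrix and solves with ``numpy.linalg.solve``
(the package uses a banded solver), and the QC oracle computes
leave-one-out Pearson correlations via ``numpy.corrcoef``.
"""

import numpy as np


def als_oracle(y, lam, p, max_iter, tol):
    """Dense-matrix asymmetric least squares baseline."""
    y = np.asarray(y, dtype=float)
    n = y.size
    D = np.diff(np.eye(n), n=2, axis=0)  # (n-2, n) second difference
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        A = np.diag(w) + penalty
        z = np.linalg.solve(A, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        changed = np.mean(w_new != w)
        w = w_new
        if changed < tol:
            break
    return z


def loo_correlations(mat):
    """Pearson correlation of each row with the mean of the other rows."""
    n = mat.shape[0]
    out = np.empty(n)
    for i in range(n):
        others = np.delete(mat, i, axis=0).mean(axis=0)
        out[i] = np.corrcoef(mat[i], others)[0, 1]
    return out


def smooth_background(rng, n):
    """A random smooth fluorescence-like background on n channels."""
    u = np.linspace(0.0, 1.0, n)
    amp = rng.uniform(500, 3000)
    tau = rng.uniform(0.2, 0.8)
    c = rng.uniform(-300, 300, size=3)
    return amp * np.exp(-u / tau) + c[0] + c[1] * u + c[2] * u**2 + 500.0
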