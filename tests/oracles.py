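"""Independent brute-force oracles used to verify the pipeline's statistics.

Each oracle is deliberately naive (pair enumeration, exact rational
arithmetic, textbook recursions, SVD instead of covariance eigensolver) and
shares no code with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, erf, sqrt

import numpy as np


def kendall_tau_brute(x, y) -> tuple[float, float]:
    """Tau-b by O(n^2) concordant/discordant pair counting, with the
    tie-corrected normal approximation for the two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
    n0 = n * (n - 1) // 2

    def tie_term(v, weight):
        _, counts = np.unique(v, return_counts=True)
        return sum(weight(int(t)) for t in counts if t > 1)

    w1 = lambda t: t * (t - 1) // 2
    n1 = tie_term(x, w1)
    n2 = tie_term(y, w1)
    denom = sqrt((n0 - n1) * (n0 - n2))
    tau = (conc - disc) / denom if denom > 0 else 0.0

    # tie-corrected variance of S = conc - disc (Kendall 1945)
    wt2 = lambda t: t * (t - 1) * (t - 2)
    wt3 = lambda t: t * (t - 1) * (2 * t + 5)
    vt = tie_term(x, wt3)
    vu = tie_term(y, wt3)
    v0 = n * (n - 1) * (2 * n + 5)
    var_s = (v0 - vt - vu) / 18.0 \
        + tie_term(x, wt2) * tie_term(y, wt2) / (9.0 * n * (n - 1) * (n - 2)) \
        + n1 * n2 / (0.5 * n * (n - 1))
    if var_s <= 0:
        return tau, 1.0
    z = (conc - disc) / sqrt(var_s)
    p = 2 * (1 - 0.5 * (1 + erf(abs(z) / sqrt(2))))
    return tau, min(1.0, p)


def bh_fdr_recursion(p_values) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up: q_(m) = p_(m);
    q_(i) = min(q_(i+1), m/i * p_(i))."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    q_sorted[m - 1] = p[order[m - 1]]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i + 1], (m / (i + 1)) * p[order[i]])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_upper_tail_exact(x: int, M: int, K: int, N: int) -> float:
    """P(X >= x) by exact rational summation of the hypergeometric pmf."""
    hi = min(K, N)
    if x <= 0:
        return 1.0
    if x > hi:
        return 0.0
    total = Fraction(0)
    denom = comb(M, N)
    for i in range(x, hi + 1):
        total += Fraction(comb(K, i) * comb(M - K, N - i), denom)
    return float(total)


def pca_svd_oracle(matrix: np.ndarray, n_components: int):
    """Loadings and eigenvalues of the column-centred covariance via SVD."""
    X = np.asarray(matrix, float)
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    evals = s ** 2 / (X.shape[0] - 1)
    loadings = vt.T[:, :n_components]
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return loadings, evals[:n_components]


def percentile_sort_interpolate(values, pct: float) -> float:
    """Linear-interpolation percentile by explicit sort and interpolation."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    h = (n - 1) * pct / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))
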