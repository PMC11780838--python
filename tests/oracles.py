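"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: NNLS is
re-solved by projected gradient, and DTW by explicit recursion over every
monotone warping path.
"""

import numpy as np


def projected_gradient_nnls(W, E, n_iter=5000):
    """min ||W C - E||_F^2 s.t. C >= 0 by projected gradient descent."""
    L = np.linalg.norm(W.T @ W, 2)
    step = 1.0 / max(L, 1e-12)
    C = np.zeros((W.shape[1], E.shape[1]))
    WtW, WtE = W.T @ W, W.T @ E
    for _ in range(n_iter):
        C = np.clip(C - step * (WtW @ C - WtE), 0.0, None)
    return C


def dtw_brute_force(a, b):
    """Minimum warping-path cost by explicit recursion (no DP table)."""
    a = list(a)
    b = list(b)

    def rec(i, j):
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return c + best

    return rec(len(a) - 1, len(b) - 1)
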