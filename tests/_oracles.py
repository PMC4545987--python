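"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the model definitions (simple
loops over a likelihood evaluated on a parameter grid) and deliberately
shares no code with the package's estimation kernel, so it can serve as an
arms-length check of the JMLE implementation.
"""

from __future__ import annotations

import numpy as np


def dichotomous_loglik(X: np.ndarray, theta: np.ndarray,
                       delta: np.ndarray) -> float:
    """Joint Rasch log-likelihood for a complete 0/1 matrix."""
    ll = 0.0
    for n in range(X.shape[0]):
        for i in range(X.shape[1]):
            e = theta[n] - delta[i]
            ll += X[n, i] * e - np.log1p(np.exp(e))
    return ll


def grid_jmle_dichotomous(X: np.ndarray, step: float = 0.01,
                          span: float = 6.0, max_sweeps: int = 200):
    """Maximize the joint likelihood by cyclic coordinate ascent on a grid.

    Each person and item parameter is in turn set to the grid value (spacing
    ``step`` over [-span, span]) that maximizes the joint likelihood with
    all other parameters held fixed, until a full sweep changes nothing.
    Returns (theta, delta) re-centred so the items average zero, the same
    identification the package reports.
    """
    X = np.asarray(X, dtype=float)
    N, I = X.shape
    grid = np.round(np.arange(-span, span + step / 2, step), 10)
    theta = np.zeros(N)
    delta = np.zeros(I)
    for _ in range(max_sweeps):
        changed = False
        for n in range(N):
            # row likelihood over candidate theta values (vectorised)
            e = grid[:, None] - delta[None, :]
            ll = (X[n] * e - np.log1p(np.exp(e))).sum(axis=1)
            best = grid[int(np.argmax(ll))]
            if best != theta[n]:
                theta[n] = best
                changed = True
        for i in range(I):
            e = theta[:, None] - grid[None, :]
            ll = (X[:, i][:, None] * e - np.log1p(np.exp(e))).sum(axis=0)
            best = grid[int(np.argmax(ll))]
            if best != delta[i]:
                delta[i] = best
                changed = True
        if not changed:
            break
    c = delta.mean()
    return theta - c, delta - c


def pcm_category_probs(theta: float, step_difficulties) -> np.ndarray:
    """Direct evaluation of partial-credit category probabilities from the
    product-of-adjacent-odds definition (independent of the package)."""
    num = [1.0]
    acc = 0.0
    for d in step_difficulties:
        acc += theta - d
        num.append(np.exp(acc))
    num = np.asarray(num)
    return num / num.sum()
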