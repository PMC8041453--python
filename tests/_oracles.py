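"""Independent oracles used by the test suite.

Deliberately naive implementations (exhaustive enumeration, pairwise sums,
lattice search) that share no code with the package internals.
"""

from itertools import product

import numpy as np


def esf_bruteforce(beta):
    """gamma_r by exhaustive enumeration of all 2^m response patterns."""
    beta = np.asarray(beta, dtype=float)
    m = beta.size
    eps = np.exp(-beta)
    gamma = np.zeros(m + 1)
    for x in product([0, 1], repeat=m):
        x = np.array(x)
        gamma[x.sum()] += np.prod(eps**x)
    return gamma


def gini_pairwise(d):
    """Gini index as the normalised mean absolute difference
    sum_{i<j} |d_i - d_j| / (m^2 * mean(d))."""
    d = np.asarray(d, dtype=float)
    m = d.size
    if d.sum() == 0:
        return 0.0
    total = sum(abs(d[i] - d[j]) for i in range(m) for j in range(i + 1, m))
    return total / (m * m * d.mean())


def criterion_on_grid(b1, b2, crit, grid):
    """Vectorised evaluation of a criterion on many shifts (dense oracle)."""
    b1, b2 = np.asarray(b1), np.asarray(b2)
    m = b1.size
    d = np.abs(b1[None, :] - b2[None, :] - np.asarray(grid)[:, None])
    if crit == "clf":
        return -d.sum(axis=1)
    ds = np.sort(d, axis=1)
    total = ds.sum(axis=1)
    weighted = ds @ np.arange(1, m + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gi = 2.0 * weighted / (m * total) - (m + 1) / m
    return np.where(total == 0, 0.0, gi)


def dense_grid_argmax(b1, b2, crit, step=1e-3):
    """Argmax of a criterion over a dense grid spanning the search interval."""
    b1, b2 = np.asarray(b1), np.asarray(b2)
    cmin = b1.min() - b2.max()
    cmax = b1.max() - b2.min()
    grid = np.arange(cmin, cmax + step, step)
    vals = criterion_on_grid(b1, b2, crit, grid)
    return grid[int(np.argmax(vals))], vals.max()


def conditional_loglik_3items(X, b2, b3):
    """Conditional Rasch log-likelihood for 3 items under sum-zero
    (b1 = -b2-b3), vectorised over lattices of (b2, b3)."""
    X = np.asarray(X)
    scores = X.sum(axis=1)
    keep = (scores > 0) & (scores < 3)
    X = X[keep]
    s = X.sum(axis=0)
    n_r = np.bincount(X.sum(axis=1), minlength=4)[1:3]
    b2, b3 = np.asarray(b2, dtype=float), np.asarray(b3, dtype=float)
    b1 = -b2 - b3
    e1, e2, e3 = np.exp(-b1), np.exp(-b2), np.exp(-b3)
    g1 = e1 + e2 + e3
    g2 = e1 * e2 + e1 * e3 + e2 * e3
    return -(s[0] * b1 + s[1] * b2 + s[2] * b3) - n_r[0] * np.log(g1) - n_r[1] * np.log(g2)


def cml_gridsearch_3items(X, span=3.0, coarse=0.01, fine=5e-4):
    """Grid-search maximiser of the 3-item conditional likelihood under the
    sum-zero restriction: coarse lattice, then refinement around the best
    coarse point.  Returns the full beta vector (b1, b2, b3)."""
    g = np.arange(-span, span + coarse, coarse)
    B2, B3 = np.meshgrid(g, g, indexing="ij")
    ll = conditional_loglik_3items(X, B2.ravel(), B3.ravel())
    i = int(np.argmax(ll))
    c2, c3 = B2.ravel()[i], B3.ravel()[i]
    g2 = np.arange(c2 - 2 * coarse, c2 + 2 * coarse + fine, fine)
    g3 = np.arange(c3 - 2 * coarse, c3 + 2 * coarse + fine, fine)
    B2, B3 = np.meshgrid(g2, g3, indexing="ij")
    ll = conditional_loglik_3items(X, B2.ravel(), B3.ravel())
    i = int(np.argmax(ll))
    b2, b3 = B2.ravel()[i], B3.ravel()[i]
    return np.array([-b2 - b3, b2, b3])
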