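"""Independent brute-force oracles shared by the test modules."""

from itertools import combinations

import numpy as np


def bp_oracle_sparse(M, y, k_max, tol=1e-9):
    """Brute-force basis pursuit for signals with at most k_max nonzeros:
    enumerate supports, least-squares fit each, keep the feasible fit
    with the smallest l1 norm."""
    c = M.shape[1]
    best, best_l1 = None, np.inf
    for k in range(k_max + 1):
        for support in combinations(range(c), k):
            x = np.zeros(c)
            if k:
                sol, *_ = np.linalg.lstsq(M[:, list(support)], y, rcond=None)
                x[list(support)] = sol
            if np.abs(M @ x - y).max() <= tol * max(np.abs(y).max(), 1.0):
                l1 = np.abs(x).sum()
                if l1 < best_l1 - 1e-12:
                    best, best_l1 = x, l1
    return best
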