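"""Independent brute-force oracles used to validate the fast implementations."""

from itertools import combinations

import numpy as np


def auc_by_pair_counting(scores, labels) -> float:
    """AUC as the fraction of (positive, negative) pairs the positive wins,
    ties counting one half -- exhaustive enumeration."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p-value by full enumeration of all
    C(n1+n2, n1) group assignments of the pooled sample (no ties assumed)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(first_idx):
        first = pooled[list(first_idx)]
        rest = np.delete(pooled, list(first_idx))
        return sum(np.sum(v > rest) for v in first)

    u_obs = u_stat(range(n1))
    us = np.array([u_stat(c) for c in combinations(range(len(pooled)), n1)])
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))
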