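"""Independent brute-force oracles used to check the fast implementations.

Each oracle recomputes a quantity from its definition (enumeration or a
dense grid), sharing no code path with the routine it validates.
"""

from itertools import combinations
from math import comb

import numpy as np


def grid_scan_pI(sequence, pka, step=0.0005):
    """Isoelectric point as the sign change of net charge on a dense pH
    grid, vectorized from residue counts (no bisection)."""
    grid = np.arange(0.0, 14.0 + step, step)
    charge = 1.0 / (1.0 + 10.0 ** (grid - pka.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - grid))
    for res, (pk, sign) in pka.side_chains.items():
        n = sequence.count(res)
        if n:
            if sign > 0:
                charge += n / (1.0 + 10.0 ** (grid - pk))
            else:
                charge -= n / (1.0 + 10.0 ** (pk - grid))
    idx = int(np.argmax(charge <= 0))
    return 0.5 * (grid[idx - 1] + grid[idx])


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact-integer hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    obs = comb(r1, a) * comb(n - r1, c1 - a)
    num = sum(
        comb(r1, k) * comb(n - r1, c1 - k)
        for k in range(lo, hi + 1)
        if comb(r1, k) * comb(n - r1, c1 - k) <= obs
    )
    return num / comb(n, c1)


def rank_sum_oracle(a, b):
    """Two-sided exact rank-sum p by enumerating every assignment of the
    pooled values to the two groups (tie-free inputs)."""
    pool = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    idx = range(len(pool))
    for subset in combinations(idx, n1):
        sa = pool[list(subset)]
        sb = pool[[i for i in idx if i not in subset]]
        us.append(sum(1 for x in sa for y in sb if x > y))
    us = np.array(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def pairwise_auc(scores, labels):
    """ROC-AUC as the fraction of concordant positive-negative pairs,
    ties counting 1/2 (O(n^2) enumeration)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
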