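"""Small independent oracles shared across test modules."""

from itertools import combinations

import numpy as np
import scipy.stats


def brute_force_bh(p):
    """Benjamini-Hochberg step-up q-values computed from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx in range(m):
        j = order[rank_idx]
        q[j] = min(m * p[order[i]] / (i + 1) for i in range(rank_idx, m))
    return np.minimum(q, 1.0)


def exact_rank_sum_p(a, b):
    """Two-sided rank-sum p by enumeration of all rank configurations."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n = len(pooled)
    na = len(a)
    observed = abs(ranks[:na].sum() - na * (n + 1) / 2)
    count = total = 0
    for idx in combinations(range(n), na):
        stat = abs(ranks[list(idx)].sum() - na * (n + 1) / 2)
        total += 1
        if stat >= observed - 1e-9:
            count += 1
    return count / total
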