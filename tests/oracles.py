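"""Independent brute-force oracles used by the test suite.

Kept deliberately naive and separate from the package: the Mann-Whitney
oracle enumerates group assignments and computes U by direct pairwise
comparison of raw values (the implementation goes through mid-rank
sums instead).
"""

import itertools
import math


def mann_whitney_enumeration_p(x, y) -> float:
    """Two-sided exact p-value by exhaustive enumeration."""
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)

    def u_stat(idx_a):
        chosen = set(idx_a)
        a = [pooled[i] for i in idx_a]
        b = [pooled[i] for i in range(n) if i not in chosen]
        return sum(
            1.0 if ai > bj else (0.5 if ai == bj else 0.0)
            for ai in a for bj in b
        )

    mu = n1 * (n - n1) / 2.0
    d_obs = abs(u_stat(tuple(range(n1))) - mu)
    hits = sum(
        1 for comb in itertools.combinations(range(n), n1)
        if abs(u_stat(comb) - mu) >= d_obs
    )
    return hits / math.comb(n, n1)
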