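"""Shared brute-force rank-test oracles, independent of the package.

Written directly from the definitions: an explicit pairwise U count,
the tie-corrected normal approximation, and exhaustive permutation
enumeration for small samples.
"""

import math
from itertools import combinations


def oracle_mwu(a, b):
    u = 0.0
    for x in a:
        for y in b:
            if x < y:
                u += 1.0
            elif x == y:
                u += 0.5
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    mu = n_a * n_b / 2
    pooled = sorted(list(a) + list(b))
    tie = 0
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        t = j - i
        tie += t**3 - t
        i = j
    var = n_a * n_b / 12 * ((n + 1) - tie / (n * (n - 1)))
    z = (u - mu) / math.sqrt(var) if var > 0 else 0.0
    p = 0.5 * math.erfc(z / math.sqrt(2)) if var > 0 else 1.0
    return u, z, p


def oracle_exact(a, b):
    """One-sided (A lower) exact permutation tail probability."""
    pooled = list(a) + list(b)
    n = len(pooled)
    u_obs = oracle_mwu(a, b)[0]
    count = total = 0
    for comb in combinations(range(n), len(a)):
        grp_a = [pooled[i] for i in comb]
        grp_b = [pooled[i] for i in range(n) if i not in comb]
        total += 1
        if oracle_mwu(grp_a, grp_b)[0] >= u_obs - 1e-9:
            count += 1
    return count / total
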