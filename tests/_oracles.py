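"""Independent recursive-descent oracles for coancestry and purged coancestry.

These evaluate the pair recursions directly (memoized, always expanding
the younger member of a pair by topological rank), independently of the
tabular implementation they are used to check.
"""

import numpy as np


def _structure(p):
    rank = np.empty(p.n, dtype=int)
    rank[p.order] = np.arange(p.n)
    parents = {
        i: (
            int(p.sire_idx[i]) if p.sire_idx[i] >= 0 else None,
            int(p.dam_idx[i]) if p.dam_idx[i] >= 0 else None,
        )
        for i in range(p.n)
    }
    return rank, parents


def kinship_recursive(p):
    """Malécot coancestry by memoized pair recursion (original id order)."""
    rank, parents = _structure(p)
    memo = {}

    def f(a, b):
        if a is None or b is None:
            return 0.0
        if rank[a] > rank[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            s, d = parents[a]
            val = 0.5 * (1.0 + (f(s, d) if s is not None and d is not None else 0.0))
        else:
            s, d = parents[b]  # b is the younger
            if s is None and d is None:
                val = 0.0
            else:
                val = 0.5 * (f(a, s) + f(a, d))
        memo[key] = val
        return val

    n = p.n
    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = f(i, j)
    return out


def purged_coancestry_recursive(p, d, F):
    """Purged coancestry by memoized pair recursion: gamma(A,B) =
    1/2[gamma(A,E)+gamma(A,H)](1-d F_B) expanding the younger member B,
    and gamma(A,A) = 1/2(1+g_A)(1-2d F_A) with g_A = gamma(sire, dam)."""
    rank, parents = _structure(p)
    memo = {}

    def gam(a, b):
        if a is None or b is None:
            return 0.0
        if rank[a] > rank[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            s, dm = parents[a]
            ga = gam(s, dm) if s is not None and dm is not None else 0.0
            val = 0.5 * (1.0 + ga) * (1.0 - 2.0 * d * F[a])
        else:
            s, dm = parents[b]
            if s is None and dm is None:
                val = 0.0
            else:
                val = 0.5 * (gam(a, s) + gam(a, dm)) * (1.0 - d * F[b])
        memo[key] = val
        return val

    n = p.n
    G = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            G[i, j] = G[j, i] = gam(i, j)
    g = np.zeros(n)
    for i in range(n):
        s, dm = parents[i]
        g[i] = gam(s, dm) if s is not None and dm is not None else 0.0
    return g, G
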