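"""Independent brute-force oracles shared by the unit and acceptance suites.

These deliberately use plain-python dynamic programming / exhaustive
enumeration, written separately from the package implementations they check.
"""

import itertools


def brute_force_local_affine(a, b, matrix, go, ge):
    """Affine-gap Smith–Waterman score by the plain three-matrix DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - ge, H[i][j - 1] - go - ge)
            F[i][j] = max(F[i - 1][j] - ge, H[i - 1][j] - go - ge)
            d = H[i - 1][j - 1] + matrix[(a[i - 1], b[j - 1])]
            H[i][j] = max(0.0, d, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def global_affine_score_oracle(a, b, matrix, go, ge):
    """Global (Needleman–Wunsch) affine-gap score, plain python."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -go - ge * j
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -go - ge * i
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - ge, H[i][j - 1] - go - ge)
            F[i][j] = max(F[i - 1][j] - ge, H[i - 1][j] - go - ge)
            H[i][j] = max(H[i - 1][j - 1] + matrix[(a[i - 1], b[j - 1])],
                          E[i][j], F[i][j])
    return H[n][m]


def brute_force_fitch(tree, site):
    """Minimum changes over all internal state assignments (exhaustive).

    ``site`` maps leaf name -> state index or None (wildcard).
    """
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = None
    for combo in itertools.product(range(4), repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))
        changes = 0
        for n in tree.postorder():
            if n.parent is None:
                continue
            s_n = site[n.name] if n.is_leaf else assign[id(n)]
            s_p = assign[id(n.parent)]
            if s_n is None:
                continue
            if s_n != s_p:
                changes += 1
        best = changes if best is None else min(best, changes)
    return best
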