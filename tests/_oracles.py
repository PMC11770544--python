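"""Independent reference implementations used only to cross-check the package.

These are deliberately written from the definitions, without reusing any
package code paths: a plain-Python Gotoh dynamic program for affine-gap
global alignment scores, and an enumerate-everything residue-rule engine.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def gotoh_global_score(a, b, score, gap_open, gap_extend):
    """Optimal global affine-gap alignment score by explicit Gotoh DP.

    ``score(x, y)`` returns the substitution score; a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``; terminal gaps are penalized.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                M[i][j] = best_prev + score(a[i - 1], b[j - 1])
            if i > 0 and j > 0:
                X[i][j] = max(
                    M[i - 1][j] - gap_open,
                    Y[i - 1][j] - gap_open,
                    X[i - 1][j] - gap_extend,
                )
            if j > 0 and i > 0:
                Y[i][j] = max(
                    M[i][j - 1] - gap_open,
                    X[i][j - 1] - gap_open,
                    Y[i][j - 1] - gap_extend,
                )
    return max(M[n][m], X[n][m], Y[n][m])


def classify_by_enumeration(profile, rules):
    """Most-constrained fully-matched rule, by brute enumeration.

    Returns a family name, "ambiguous" (>=2 fully matched rules at the
    maximal constraint count), or "unclassified".
    """
    diag = profile.diagnostic()
    matched = []
    for rule in rules:
        ok = True
        for pos, allowed in rule.allowed:
            residue = diag[pos]
            if residue is None or residue not in allowed:
                ok = False
                break
        if ok:
            matched.append(rule)
    if not matched:
        return "unclassified"
    best_n = max(r.n_constrained for r in matched)
    top = [r for r in matched if r.n_constrained == best_n]
    if len(top) > 1:
        return "ambiguous"
    return top[0].family
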