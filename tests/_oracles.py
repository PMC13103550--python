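"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately re-derives the quantity along a different code
path from the implementation it checks (linear programming, exhaustive
enumeration, naive running sums).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog


def dip_lp_oracle(x) -> float:
    """Minimax distance from the ECDF to the closest unimodal CDF, by LP.

    A unimodal distribution function is convex left of its mode, concave
    right of it, with an optional atom at the mode. For each candidate mode
    placement (at a data value, with atom; or interior to a gap between
    adjacent values) the best piecewise-linear unimodal fit restricted to
    the sample points is a small linear program in the knot values; the dip
    is the minimum over placements of the optimal sup deviation.
    """
    arr = np.sort(np.asarray(x, dtype=float))
    u, counts = np.unique(arr, return_counts=True)
    m = len(u)
    n = len(arr)
    F = np.cumsum(counts) / n  # ECDF value at each knot
    L = F - counts / n  # ECDF left limit at each knot

    # Mode at knot k (optionally with an atom there). A mode interior to a
    # gap between data values reduces to one of the adjacent knot configs:
    # the concave branch right of the mode forces the gap segment's mean
    # slope to be at least the next segment's slope (and mirrored on the
    # convex side), which is exactly the knot config's curvature
    # constraint, so enumerating knots covers interior modes too.
    best = np.inf
    for k in range(m):
        for atom in (None, k):
            val = _dip_lp_config(u, F, L, convex_upto=k, concave_from=k, atom_at=atom)
            best = min(best, val)
    return best


def _dip_lp_config(u, F, L, convex_upto, concave_from, atom_at):
    """Solve one mode-placement LP.

    Variables: w_0..w_{m-1} (CDF values at knots), optional ell (left limit
    at the atom knot), t (the sup deviation). Convexity second-difference
    constraints apply at internal knots strictly inside the convex region
    (both adjacent segments left of the mode), concavity likewise on the
    right.
    """
    m = len(u)
    has_atom = atom_at is not None
    n_var = m + (1 if has_atom else 0) + 1
    t_idx = n_var - 1
    ell_idx = m  # only meaningful when has_atom

    A_ub, b_ub = [], []

    def row(pairs, rhs):
        r = np.zeros(n_var)
        for idx, coef in pairs:
            r[idx] += coef
        A_ub.append(r)
        b_ub.append(rhs)

    def left_val_idx(i):
        # value used as the RIGHT end of segment (i-1 -> i): the left limit
        # at knot i, which is ell at the atom knot and w_i elsewhere.
        return ell_idx if (has_atom and i == atom_at) else i

    # monotonicity: w_{i} <= leftlimit_{i+1} <= w_{i+1}
    for i in range(m - 1):
        nxt = left_val_idx(i + 1)
        row([(i, 1.0), (nxt, -1.0)], 0.0)
        if nxt != i + 1:
            row([(nxt, 1.0), (i + 1, -1.0)], 0.0)

    def slope(i, sign):
        # coefficient pairs for sign * slope of segment i -> i+1
        dx = u[i + 1] - u[i]
        a = i  # left end is the knot value (atoms only jump upward)
        b = left_val_idx(i + 1)
        return [(b, sign / dx), (a, -sign / dx)]

    # convexity at knots whose two flanking segments both lie in the convex
    # region (knots 1..convex_upto-1): slope(i-1->i) - slope(i->i+1) <= 0
    for i in range(1, max(convex_upto, 0)):
        row(slope(i - 1, 1.0) + slope(i, -1.0), 0.0)
    # concavity mirror on the right (knots concave_from+1 .. m-2)
    for i in range(concave_from + 1, m - 1):
        row(slope(i - 1, -1.0) + slope(i, 1.0), 0.0)

    # deviation constraints at each knot: |value - F_i| <= t and
    # |leftlimit - L_i| <= t
    for i in range(m):
        row([(i, 1.0), (t_idx, -1.0)], F[i])
        row([(i, -1.0), (t_idx, -1.0)], -F[i])
        li = left_val_idx(i)
        row([(li, 1.0), (t_idx, -1.0)], L[i])
        row([(li, -1.0), (t_idx, -1.0)], -L[i])
    if has_atom:
        # atom jumps upward: ell <= w_k; ell above previous knot
        row([(ell_idx, 1.0), (atom_at, -1.0)], 0.0)
        if atom_at > 0:
            row([(atom_at - 1, 1.0), (ell_idx, -1.0)], 0.0)

    bounds = [(0.0, 1.0)] * (n_var - 1) + [(0.0, None)]
    c = np.zeros(n_var)
    c[t_idx] = 1.0
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds, method="highs")
    if not res.success:
        return np.inf
    return float(res.fun)


def gsea_es_bruteforce(scores, in_set, weight_exponent=1.0):
    """Naive running-sum enrichment score for an already-ranked score list.

    ``in_set`` is a boolean mask aligned with ``scores`` (descending).
    Hit steps are |score|^w normalized over hits; miss steps are uniform.
    Returns the signed maximum deviation of the running sum.
    """
    scores = np.asarray(scores, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = len(scores)
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("degenerate set")
    w = np.abs(scores) ** weight_exponent
    hit_total = w[in_set].sum()
    running = 0.0
    pos_max, neg_min = 0.0, 0.0
    for i in range(n):
        if in_set[i]:
            running += w[i] / hit_total
        else:
            running -= 1.0 / (n - n_hit)
        pos_max = max(pos_max, running)
        neg_min = min(neg_min, running)
    # convention: on a magnitude tie the positive deviation wins
    return pos_max if abs(pos_max) >= abs(neg_min) - 1e-12 else neg_min


def hypergeom_tail_enumeration(N, K, n, k):
    """P(overlap >= k) by direct combinatorial summation."""
    total = math.comb(N, n)
    acc = 0
    for kk in range(k, min(K, n) + 1):
        acc += math.comb(K, kk) * math.comb(N - K, n - kk)
    return acc / total


def bh_stepup_reference(p):
    """Plain-loop Benjamini-Hochberg step-up, independent of the
    vectorized implementation."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def spearman_exact_null_p(x, y):
    """Two-sided permutation p-value for Spearman rho at tiny n, with
    average ranks for ties; exact enumeration over all orderings of y."""
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = rankdata(x)

    def rho_of(vals):
        ry = rankdata(vals)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        return float((rxc * ryc).sum() / denom)

    observed = abs(rho_of(y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(rho_of(np.array(perm))) >= observed - 1e-12:
            count += 1
    return count / total
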