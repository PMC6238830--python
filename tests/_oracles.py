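"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: frequent item sets
by exhaustive subset enumeration, the exact-test p-value by direct
hypergeometric enumeration with exact integer binomials, and the
conditional-MLE odds ratio by likelihood evaluation on a dense grid.
"""

from fractions import Fraction
from itertools import combinations
from math import comb, exp, log


def enumerate_frequent_itemsets(transactions, min_support_pct, max_size=None):
    """All frequent item sets by checking every subset of the item universe.

    Returns {frozenset(items): count}.
    """
    universe = sorted(
        {i for t in transactions for i in t.items}, key=lambda i: i.value_label
    )
    n = len(transactions)
    min_count = -(-min_support_pct * n // 100)  # ceil
    top = len(universe) if max_size is None else min(max_size, len(universe))
    out = {}
    for size in range(1, top + 1):
        for subset in combinations(universe, size):
            s = frozenset(subset)
            c = sum(1 for t in transactions if s <= t.items)
            if c >= min_count:
                out[s] = c
    return out


def hypergeom_point_probs(a, b, c, d):
    """Exact central hypergeometric pmf over the support, as Fractions."""
    r1, r2, c1 = a + b, c + d, a + c
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    total = sum(comb(r1, k) * comb(r2, c1 - k) for k in range(kmin, kmax + 1))
    return {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), total)
        for k in range(kmin, kmax + 1)
    }


def fisher_p_enumeration(a, b, c, d):
    """Two-sided point-probability p by exact enumeration."""
    probs = hypergeom_point_probs(a, b, c, d)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def conditional_mle_grid(a, b, c, d, n_grid=20001, span=20.0):
    """Argmax of the noncentral hypergeometric likelihood on a dense log-psi grid."""
    import numpy as np

    r1, r2, c1 = a + b, c + d, a + c
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    if a == kmin:
        return 0.0
    if a == kmax:
        return float("inf")
    ks = np.arange(kmin, kmax + 1)
    log_terms = np.array([log(comb(r1, k)) + log(comb(r2, c1 - k)) for k in ks])
    ts = np.linspace(-span, span, n_grid)
    lw = log_terms[None, :] + np.outer(ts, ks)  # (grid, support)
    m = lw.max(axis=1, keepdims=True)
    log_denom = (m + np.log(np.exp(lw - m).sum(axis=1, keepdims=True))).ravel()
    ll = log_terms[ks == a][0] + a * ts - log_denom
    return float(exp(ts[int(np.argmax(ll))]))
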