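"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths: the Kendall null
is obtained by enumerating permutations, and the hypergeometric tail by
summing binomial coefficients.
"""

import itertools
from collections import Counter
from math import comb

import numpy as np


def kendall_s_naive(x, ref):
    s = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(x[i] - x[j])) * int(np.sign(ref[i] - ref[j]))
    return s


def null_by_enumeration(x_values, ref_values):
    """Distribution of S over all n! orderings of the x multiset.

    Returns a dict S -> probability.  Enumerating duplicate permutations
    of tied values multiple times leaves the distribution unchanged.
    """
    n = len(x_values)
    iu = np.triu_indices(n, 1)
    ref = np.asarray(ref_values, dtype=float)
    sr = np.sign(ref[iu[0]] - ref[iu[1]])
    counts = Counter()
    total = 0
    for perm in itertools.permutations(x_values):
        pa = np.asarray(perm, dtype=float)
        sx = np.sign(pa[iu[0]] - pa[iu[1]])
        counts[int(np.dot(sx, sr))] += 1
        total += 1
    return {s: c / total for s, c in counts.items()}


def pvalue_by_enumeration(s_obs, x_values, ref_values):
    dist = null_by_enumeration(x_values, ref_values)
    return sum(p for s, p in dist.items() if abs(s) >= abs(s_obs))


def null_by_enumeration_vec(x_values, ref_values):
    """Vectorised version of :func:`null_by_enumeration` (n <= 8)."""
    n = len(x_values)
    perms = np.array(list(itertools.permutations(np.asarray(x_values, float))))
    iu = np.triu_indices(n, 1)
    ref = np.asarray(ref_values, dtype=float)
    sr = np.sign(ref[iu[0]] - ref[iu[1]])
    sx = np.sign(perms[:, iu[0]] - perms[:, iu[1]])
    s = (sx * sr).sum(axis=1).astype(int)
    vals, counts = np.unique(s, return_counts=True)
    total = len(perms)
    return {int(v): c / total for v, c in zip(vals, counts)}


def hypergeom_tail(k, n_bg, n_marked, n_draw):
    """P(X >= k) for X ~ Hypergeometric(N=n_bg, K=n_marked, n=n_draw)."""
    denom = comb(n_bg, n_draw)
    upper = min(n_marked, n_draw)
    return sum(
        comb(n_marked, i) * comb(n_bg - n_marked, n_draw - i)
        for i in range(k, upper + 1)
    ) / denom


def values_from_pattern(pattern):
    """A concrete value vector realising a tie pattern (ascending)."""
    vals = []
    for level, size in enumerate(pattern):
        vals.extend([float(level)] * size)
    return vals
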