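"""Independent brute-force oracles shared by the test suite."""

import itertools

import numpy as np


def exact_ranksum_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free data).

    Enumerates every assignment of the pooled values into groups of the
    observed sizes and counts assignments at least as extreme (in |U -
    E[U]|) as observed.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    center = n_a * (n - n_a) / 2.0
    u_obs = sum(x > y for x in a for y in b)
    hits = total = 0
    for picks in itertools.combinations(range(n), n_a):
        grp = pooled[list(picks)]
        rest = np.delete(pooled, list(picks))
        u = sum(x > y for x in grp for y in rest)
        total += 1
        if abs(u - center) >= abs(u_obs - center):
            hits += 1
    return hits / total


def pair_counting_auc(scores, labels):
    """AUC by direct pair counting: (#concordant + 0.5 #ties) / #pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def bh_step_up_oracle(p):
    """Hand implementation of the BH step-up q-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = prev
    return q


def t_cdf_closed_form(t, df):
    """Student-t CDF for df 1 and 2 in closed form."""
    if df == 1:
        return 0.5 + np.arctan(t) / np.pi
    if df == 2:
        return 0.5 * (1.0 + t / np.sqrt(2.0 + t * t))
    raise ValueError("closed form implemented for df in {1, 2}")
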