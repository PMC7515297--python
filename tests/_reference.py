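"""Naive pure-Python reference implementations used as test oracles.

Deliberately slow and direct: full pairwise distance tables, exhaustive
scans over every admissible neighbor count, explicit pair counting for
the AUC.  These stay independent of the vectorized library code paths
they are used to check.
"""

from __future__ import annotations

import math


def naive_neighbor_order(values, query):
    """All other sample indices sorted by (Euclidean distance, index)."""
    n = len(values)
    dists = []
    for j in range(n):
        if j == query:
            continue
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(values[query], values[j])))
        dists.append((d, j))
    dists.sort()
    return [j for _, j in dists]


def naive_entropy(values, labels, k_max=None):
    """Balanced nearest-neighbor cross-entropy, fully exhaustive."""
    n = len(values)
    cap = n - 1 if k_max is None else min(k_max, n - 1)
    log_e = []
    for i in range(n):
        order = naive_neighbor_order(values, i)
        best_e = -1.0
        for k in range(1, cap + 1):
            same = sum(1 for j in order[:k] if labels[j] == labels[i])
            e = (same + 1) / (k + 2)
            if e > best_e:  # strict: ties keep the smallest K
                best_e = e
        log_e.append((labels[i], math.log(best_e)))
    n_a = sum(1 for lab in labels if lab == "A")
    n_b = n - n_a
    h_a = -sum(le for lab, le in log_e if lab == "A") / n_a
    h_b = -sum(le for lab, le in log_e if lab == "B") / n_b
    return h_a + h_b


def naive_max_pool_size(i, n_e):
    """Largest m with C(m, i+1) <= n_e by upward scanning."""
    m = i + 1
    while math.comb(m + 1, i + 1) <= n_e:
        m += 1
    return m


def naive_auc(scores, labels):
    """All-pairs concordance count, ties worth 1/2."""
    pos = [s for s, lab in zip(scores, labels) if lab == "A"]
    neg = [s for s, lab in zip(scores, labels) if lab == "B"]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
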