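"""Independent reference implementations used only to check the package.

Everything here is written with explicit scalar loops and no shared code
with the package, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def mat_mul(x, y):
    """Triple-loop matrix product."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = x.shape
    k2, m = y.shape
    assert k == k2
    out = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            acc = 0.0
            for t in range(k):
                acc += x[i, t] * y[t, j]
            out[i, j] = acc
    return out


def naive_bnetwalk(b, c, l_trans, beta, s):
    """Scalar-loop inter-network walk: normalize priors, s mixing steps, compose."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ml = b / b.sum()
    ld = c / c.sum()
    for _ in range(s):
        ml = beta * mat_mul(ml, l_trans) + (1.0 - beta) * b
        ld = beta * mat_mul(l_trans, ld) + (1.0 - beta) * c
    return mat_mul(ml, ld)


def naive_tcrwmda(a, m_trans, d_trans, r_prior, alpha, lam, l, r, combine="sum", a_restart=None):
    """Scalar-loop unbalanced walk.  ``a_restart`` lets the restart term use a
    different association matrix than the initialization (structural checks)."""
    a = np.asarray(a, dtype=float)
    if a_restart is None:
        a_restart = a
    a_restart = np.asarray(a_restart, dtype=float)
    r_prior = np.asarray(r_prior, dtype=float)
    md = a / a.sum()
    restart = (1.0 - alpha) * (lam * r_prior + (1.0 - lam) * a_restart)
    for t in range(1, max(l, r) + 1):
        terms = []
        if t <= l:
            terms.append(alpha * mat_mul(m_trans, md) + restart)
        if t <= r:
            terms.append(alpha * mat_mul(md, d_trans) + restart)
        total = terms[0].copy()
        for extra in terms[1:]:
            total = total + extra
        md = total / len(terms) if combine == "mean" else total
    return md


def naive_auc(scores, labels):
    """All-pairs concordance: concordant + half ties over pos*neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def naive_d1_paths(dag, delta):
    """Exhaustive-path model-1 contributions: max over all root-to-node paths
    of delta^pathlength (edges followed child -> parent)."""
    best = {dag.root: 1.0}
    stack = [(dag.root, 1.0)]
    while stack:
        node, value = stack.pop()
        for parent in dag.graph.successors(node):
            cand = value * delta
            if cand > best.get(parent, -1.0):
                best[parent] = cand
            # always continue: a longer path through parent may still win at
            # a later node when delta == 1
            stack.append((parent, cand))
    return best
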