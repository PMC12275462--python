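"""Independent slow oracles the fast implementations are checked against.

These deliberately avoid the package's pruning/eigendecomposition code
paths: matrix exponentials come from scipy.linalg.expm and the
likelihood is a brute-force sum over all internal-node state
assignments.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

MISSING_CODES = (4, 5)


def brute_force_loglik(
    model,
    seqs: dict[str, str],
    rho: float = 1.0,
    lam: float = 1.0,
    fg_branches: frozenset[int] = frozenset(),
) -> float:
    """Sum over all internal-node state assignments, column by column."""
    tree = model.tree
    code = {c: i for i, c in enumerate("ACGT")}
    P = []
    for v in range(tree.n_nodes):
        t = tree.lengths[v] * rho * (lam if v in fg_branches else 1.0)
        P.append(expm(model.Q * t))
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tips = {v: seqs[tree.names[v]] for v in tree.tip_ids}
    length = len(next(iter(tips.values())))
    total = 0.0
    for col in range(length):
        col_lik = 0.0
        for states in itertools.product(range(4), repeat=len(internal)):
            assign = dict(zip(internal, states))
            prob = model.pi[assign[tree.root]]
            for v in range(tree.n_nodes):
                p = tree.parent[v]
                if p < 0:
                    continue
                if tree.is_tip(v):
                    c = tips[v][col].upper()
                    if c in "N-":
                        continue  # marginalized: sums to 1
                    prob_v = P[v][assign[p], code[c]]
                else:
                    prob_v = P[v][assign[p], assign[v]]
                prob *= prob_v
            col_lik += prob
        total += np.log(col_lik)
    return total


def bm_covariance(tree) -> np.ndarray:
    """Analytic tip covariance under Brownian motion: shared path length."""
    n = len(tree.tip_ids)
    # root-to-node path sets
    paths = {}
    for v in tree.tip_ids:
        path = []
        u = int(v)
        while tree.parent[u] >= 0:
            path.append(u)
            u = int(tree.parent[u])
        paths[int(v)] = set(path)
    C = np.zeros((n, n))
    for i, a in enumerate(tree.tip_ids):
        for j, b in enumerate(tree.tip_ids):
            shared = paths[int(a)] & paths[int(b)]
            C[i, j] = sum(tree.lengths[v] for v in shared)
    return C


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p by direct hypergeometric tail sum."""
    from math import comb

    n_with = a + c
    n_sig = a + b
    total = a + b + c + d
    denom = comb(total, n_sig)
    p = 0.0
    for k in range(a, min(n_with, n_sig) + 1):
        p += comb(n_with, k) * comb(total - n_with, n_sig - k) / denom
    return p
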