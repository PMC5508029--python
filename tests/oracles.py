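"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by exhaustive enumeration or
direct counting, deliberately avoiding the code paths it is used to
check.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def substitution_score(a: str, b: str) -> float:
    """BLOSUM62 entry with the toolkit's neutral-X convention."""
    if a == "X" or b == "X":
        return 0.0
    return float(_BLOSUM62[a, b])


def enumerate_global_score(
    seq_a: str, seq_b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Best global affine-gap alignment score by exhaustive recursion.

    A gap of length L costs gap_open + (L - 1) * gap_extend.  Exponential
    in sequence length; intended for sequences of <= 6 residues.
    """

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(seq_a) and j == len(seq_b):
            return 0.0
        best = -np.inf
        if i < len(seq_a) and j < len(seq_b):
            best = max(
                best,
                substitution_score(seq_a[i], seq_b[j]) + rec(i + 1, j + 1, "M"),
            )
        if i < len(seq_a):
            cost = gap_extend if prev == "D" else gap_open
            best = max(best, -cost + rec(i + 1, j, "D"))
        if j < len(seq_b):
            cost = gap_extend if prev == "I" else gap_open
            best = max(best, -cost + rec(i, j + 1, "I"))
        return best

    return rec(0, 0, "")


def mbbh_oracle(score_fn, ids_a, ids_b, n, dom_a, dom_b, keep_unannotated=True):
    """Re-derive the MBBH pair set by scoring all pairs, ranking with the
    (-score, id) tie rule, and applying reciprocity + domain filters."""

    def topn(query, others, scores):
        ranked = sorted(others, key=lambda t: (-scores[t], t))
        return set(ranked[:n])

    ab = {p: {q: score_fn(p, q) for q in ids_b} for p in ids_a}
    top_ab = {p: topn(p, ids_b, ab[p]) for p in ids_a}
    top_ba = {q: topn(q, ids_a, {p: ab[p][q] for p in ids_a}) for q in ids_b}
    pairs = set()
    for p in ids_a:
        for q in top_ab[p]:
            if p not in top_ba[q]:
                continue
            arch_p, arch_q = dom_a.get(p), dom_b.get(q)
            if arch_p is None or arch_q is None:
                if keep_unannotated:
                    pairs.add((p, q))
                continue
            if set(arch_p.domain_ids) & set(arch_q.domain_ids):
                pairs.add((p, q))
    return pairs


def hypergeom_tail_enum(k: int, big_k: int, n: int, n_univ: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct summation of the
    probability mass function written with binomial coefficients."""
    from math import comb

    denom = comb(n_univ, n)
    upper = min(big_k, n)
    return sum(
        comb(big_k, x) * comb(n_univ - big_k, n - x) for x in range(k, upper + 1)
    ) / denom


def local_clustering_by_triangles(adj: dict) -> dict:
    """Local clustering coefficients by direct neighbour-pair counting."""
    out = {}
    for v, nbrs in adj.items():
        nbrs = set(nbrs)
        d = len(nbrs)
        if d < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(sorted(nbrs), 2) if b in adj[a]
        )
        out[v] = 2.0 * links / (d * (d - 1))
    return out


def bh_stepup(p):
    """Hand-rolled Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
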