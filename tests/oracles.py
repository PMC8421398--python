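"""Independent oracle implementations used only by the tests.

These deliberately avoid the package's computational paths: RED is
evaluated by a direct top-down recursion with brute-force path sums, and
global alignment scores come from a self-contained Gotoh dynamic program
rather than Bio.Align.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices


def red_naive(tree) -> dict[str, float]:
    """RED by definition: for each node, the mean parent-to-leaf distance is
    recomputed from scratch by walking every leaf path."""

    def leaves_under(nd):
        return list(nd.leaf_iter())

    def path_len(anc, nd):
        total = 0.0
        while nd is not anc:
            total += nd.edge.length or 0.0
            nd = nd.parent_node
        return total

    red: dict[str, float] = {}

    def walk(nd, parent_red):
        if nd is tree.seed_node:
            red[nd.node_id] = 0.0
        elif nd.is_leaf():
            red[nd.node_id] = 1.0
        else:
            leaves = leaves_under(nd)
            u = sum(path_len(nd.parent_node, lf) for lf in leaves) / len(leaves)
            d = nd.edge.length or 0.0
            red[nd.node_id] = parent_red if u == 0 else parent_red + (d / u) * (1 - parent_red)
        for c in nd.child_nodes():
            walk(c, red[nd.node_id])

    walk(tree.seed_node, 0.0)
    return red


_NEG = -math.inf


def gotoh_global_score(a: str, b: str, matrix_name: str = "BLOSUM62",
                       gap_open: float = -11.0, gap_extend: float = -1.0) -> float:
    """Global alignment score with affine gaps (first gap residue costs
    gap_open, each further residue gap_extend), end gaps penalized."""
    sub = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def medoid_brute_force(seqs: dict[str, str], matrix_name: str = "BLOSUM62",
                       gap_open: float = -11.0, gap_extend: float = -1.0) -> str:
    """Full pairwise scan with the Gotoh oracle and the same distance
    normalization d = 1 - S(a,b)/max(S(a,a), S(b,b))."""
    ids = sorted(seqs)
    self_score = {i: gotoh_global_score(seqs[i], seqs[i], matrix_name, gap_open, gap_extend)
                  for i in ids}
    sums = dict.fromkeys(ids, 0.0)
    for i, p in enumerate(ids):
        for q in ids[i + 1:]:
            s = gotoh_global_score(seqs[p], seqs[q], matrix_name, gap_open, gap_extend)
            d = 1.0 - s / max(self_score[p], self_score[q])
            sums[p] += d
            sums[q] += d
    best = min(sums.values())
    return min(i for i in ids if sums[i] == best)


def random_protein(rng, lo: int = 30, hi: int = 60) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[k] for k in rng.integers(0, 20, int(rng.integers(lo, hi + 1))))
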