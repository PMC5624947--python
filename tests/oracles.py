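"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: alignment scores come
from exhaustive path enumeration, pattern matching from a quadratic scan,
UPGMA from the textbook O(N^3) algorithm, and SP scoring from explicit
pair-set intersection.
"""

from __future__ import annotations

import numpy as np


# --- exhaustive global affine alignment ------------------------------------

def _all_paths(la: int, lb: int):
    """Every monotone alignment path as a string of ops over {D, U, L}."""
    stack = [(0, 0, "")]
    while stack:
        i, j, ops = stack.pop()
        if i == la and j == lb:
            yield ops
            continue
        if i < la and j < lb:
            stack.append((i + 1, j + 1, ops + "D"))
        if i < la:
            stack.append((i + 1, j, ops + "U"))
        if j < lb:
            stack.append((i, j + 1, ops + "L"))


def score_alignment_ops(ops: str, a: str, b: str, matrix, gaps) -> int:
    """Score one alignment path: substitutions plus per-run affine gap costs."""
    score = 0
    i = j = 0
    prev = None
    for op in ops:
        if op == "D":
            score += matrix.score(a[i], b[j])
            i += 1
            j += 1
        else:
            score -= gaps.gap_extend if prev == op else gaps.gap_open
            if op == "U":
                i += 1
            else:
                j += 1
        prev = op
    return score


def brute_force_alignment_score(a: str, b: str, matrix, gaps) -> int:
    """Optimal global affine score by enumerating every alignment."""
    return max(
        score_alignment_ops(ops, a, b, matrix, gaps) for ops in _all_paths(len(a), len(b))
    )


def score_emitted_alignment(row_a: str, row_b: str, matrix, gaps) -> int:
    """Re-score an emitted two-row alignment column by column."""
    ops = []
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            ops.append("D")
        elif y == "-":
            ops.append("U")
        else:
            ops.append("L")
    a = row_a.replace("-", "")
    b = row_b.replace("-", "")
    return score_alignment_ops("".join(ops), a, b, matrix, gaps)


# --- naive multi-pattern scan -----------------------------------------------

def naive_multi_scan(patterns: list[str], text: str) -> list[tuple[int, int]]:
    hits = []
    for idx, p in enumerate(patterns):
        for pos in range(len(text) - len(p) + 1):
            if text[pos : pos + len(p)] == p:
                hits.append((idx, pos))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


# --- textbook O(N^3) UPGMA ---------------------------------------------------

def naive_upgma(ids: list[str], d: np.ndarray):
    """Full-scan UPGMA; returns nested (children, height) tuples.

    Tie-break: lowest (i, j) pair in row-major order over the upper
    triangle of active clusters.
    """
    d = d.astype(float).copy()
    n = len(ids)
    active = list(range(n))
    nodes = {i: (ids[i], 0.0) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    while len(active) > 1:
        best = None
        for x in range(len(active)):
            for y in range(x + 1, len(active)):
                i, j = active[x], active[y]
                if best is None or d[i, j] < best[0]:
                    best = (d[i, j], i, j)
        _, i, j = best
        h = d[i, j] / 2.0
        nodes[i] = ((nodes[i], nodes[j]), h)
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (
                    sizes[i] + sizes[j]
                )
        sizes[i] += sizes[j]
        active.remove(j)
    return nodes[active[0]]


def tree_shape(node) -> tuple:
    """Canonical (children..., height) tuple for a package GuideTree node."""
    if node.is_leaf:
        return (node.name, 0.0)
    left, right = node.children
    return ((tree_shape(left), tree_shape(right)), round(node.height, 9))


def naive_shape(node) -> tuple:
    payload, h = node
    if isinstance(payload, str):
        return (payload, 0.0)
    left, right = payload
    return ((naive_shape(left), naive_shape(right)), round(h, 9))


# --- pair-set SP score -------------------------------------------------------

def alignment_pair_set(rows: list[tuple[str, str]]) -> set:
    """All aligned residue pairs ((idA, residue index), (idB, residue index))."""
    counters = {rid: 0 for rid, _ in rows}
    pairs = set()
    width = len(rows[0][1])
    for j in range(width):
        present = []
        for rid, row in rows:
            if row[j] != "-":
                present.append((rid, counters[rid]))
                counters[rid] += 1
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                pairs.add(frozenset((present[x], present[y])))
    return pairs


def naive_sp_score(test_rows, ref_rows) -> float:
    ref = alignment_pair_set(ref_rows)
    test = alignment_pair_set(test_rows)
    return len(ref & test) / len(ref)
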