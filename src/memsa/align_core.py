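"""Pairwise/profile affine-gap dynamic programming and UPGMA guide trees.

The DP is the three-layer (Gotoh) formulation: one layer for substitution
states and one for each gap direction.  Alongside the score layers, a
*branch matrix* of the same (m+1) x (n+1) shape records, per layer and
cell, the layer the optimum came from, so one optimal alignment is
recovered by walking the branch matrix without recomputation.  All scores
are integers (profile column scores are kept integral by scaling the gap
penalties by the product of the profile sizes).

Guide trees are built by UPGMA over k-mer distances.  The naive UPGMA is
O(N^3); maintaining a per-row reference to each row's minimum entry makes
every merge O(N), giving O(N^2) total, with results identical to the naive
algorithm under the row-major tie-break.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence, Union

import numpy as np

from .score_model import ALPHABET, GapModel, SubstitutionMatrix
from .seqio import GAP, Alignment, SequenceRecord
from .topology import SegmentedSequence

_RES_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_NEG = -(1 << 60)

# Branch / traceback codes: D = diagonal (substitution), U = up (gap in the
# second sequence/profile), L = left (gap in the first).
OP_DIAG, OP_UP, OP_LEFT = "D", "U", "L"


# ---------------------------------------------------------------------------
# Core affine DP engine
# ---------------------------------------------------------------------------

def affine_dp(
    colscore: np.ndarray, gap_open: int, gap_extend: int, free_ends: bool = False
) -> tuple[int, str]:
    """Globally align two indexed sequences/profiles.

    ``colscore[i, j]`` is the (integer) score of aligning position i of the
    first input with position j of the second.  Returns the optimal score
    and the traceback op string over {D, U, L}, recovered solely from the
    branch matrices.  By default terminal gaps are penalized like internal
    ones (true global alignment); with ``free_ends`` leading and trailing
    gaps are free (semi-global), which lets region slots shift register
    when their predicted boundaries disagree by a residue or two.
    Tie-break: D > U > L (substitutions preferred, then gaps in the second
    input).
    """
    m, n = colscore.shape
    if m == 0 and n == 0:
        return 0, ""
    cs = colscore.tolist()
    go, ge = int(gap_open), int(gap_extend)

    # score layers
    M = [[_NEG] * (n + 1) for _ in range(m + 1)]
    X = [[_NEG] * (n + 1) for _ in range(m + 1)]  # gap in second input (U)
    Y = [[_NEG] * (n + 1) for _ in range(m + 1)]  # gap in first input (L)
    # branch layers: predecessor layer code per cell
    bM = [[""] * (n + 1) for _ in range(m + 1)]
    bX = [[""] * (n + 1) for _ in range(m + 1)]
    bY = [[""] * (n + 1) for _ in range(m + 1)]

    M[0][0] = 0
    for i in range(1, m + 1):
        X[i][0] = 0 if free_ends else -(go + (i - 1) * ge)
        bX[i][0] = "M" if i == 1 else "X"
    for j in range(1, n + 1):
        Y[0][j] = 0 if free_ends else -(go + (j - 1) * ge)
        bY[0][j] = "M" if j == 1 else "Y"

    for i in range(1, m + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        bMi, bXi, bYi = bM[i], bX[i], bY[i]
        csrow = cs[i - 1]
        for j in range(1, n + 1):
            # substitution layer
            a, b, c = Mp[j - 1], Xp[j - 1], Yp[j - 1]
            if a >= b and a >= c:
                best, src = a, "M"
            elif b >= c:
                best, src = b, "X"
            else:
                best, src = c, "Y"
            Mi[j] = best + csrow[j - 1]
            bMi[j] = src
            # gap in second input (consume i)
            a, b, c = Mp[j] - go, Xp[j] - ge, Yp[j] - go
            if a >= b and a >= c:
                Xi[j], bXi[j] = a, "M"
            elif b >= c:
                Xi[j], bXi[j] = b, "X"
            else:
                Xi[j], bXi[j] = c, "Y"
            # gap in first input (consume j)
            a, b, c = Mi[j - 1] - go, Xi[j - 1] - go, Yi[j - 1] - ge
            if a >= b and a >= c:
                Yi[j], bYi[j] = a, "M"
            elif b >= c:
                Yi[j], bYi[j] = b, "X"
            else:
                Yi[j], bYi[j] = c, "Y"

    def best_layer(i: int, j: int) -> tuple[int, str]:
        a, b, c = M[i][j], X[i][j], Y[i][j]
        if a >= b and a >= c:
            return a, "M"
        if b >= c:
            return b, "X"
        return c, "Y"

    tail: list[str] = []
    if free_ends:
        # trailing gaps are free: end anywhere on the last row/column,
        # preferring the corner, then the cell nearest to it.
        score, layer, i, j = *best_layer(m, n), m, n
        for ii in range(m - 1, 0, -1):
            v, lay = best_layer(ii, n)
            if v > score:
                score, layer, i, j = v, lay, ii, n
        for jj in range(n - 1, 0, -1):
            v, lay = best_layer(m, jj)
            if v > score:
                score, layer, i, j = v, lay, m, jj
        tail = [OP_UP] * (m - i) + [OP_LEFT] * (n - j)
    else:
        score, layer = best_layer(m, n)
        i, j = m, n

    ops: list[str] = []
    while i > 0 or j > 0:
        if layer == "M":
            ops.append(OP_DIAG)
            layer = bM[i][j]
            i, j = i - 1, j - 1
        elif layer == "X":
            ops.append(OP_UP)
            layer = bX[i][j]
            i -= 1
        else:
            ops.append(OP_LEFT)
            layer = bY[i][j]
            j -= 1
    ops.reverse()
    ops.extend(tail)
    return score, "".join(ops)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

class Profile:
    """A set of gapped member rows of equal width with per-column counts.

    ``counts`` has one row per column and one column per alphabet letter
    (gaps excluded); column counts plus the column's gap count sum to the
    number of members.
    """

    def __init__(self, rows: list[tuple[str, str]]):
        if not rows:
            raise ValueError("empty profile")
        width = len(rows[0][1])
        for rid, row in rows:
            if len(row) != width:
                raise ValueError(f"profile row {rid!r} has inconsistent width")
        self.rows = rows
        counts = np.zeros((width, len(ALPHABET)), dtype=np.int64)
        for _, row in rows:
            for j, c in enumerate(row):
                if c != GAP:
                    counts[j, _RES_INDEX[c]] += 1
        self.counts = counts

    @classmethod
    def from_sequence(cls, record_id: str, residues: str) -> "Profile":
        return cls([(record_id, residues)])

    @classmethod
    def from_alignment(cls, alignment: Alignment) -> "Profile":
        return cls(list(alignment.rows))

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def n_members(self) -> int:
        return len(self.rows)

    def to_alignment(self, column_labels: list[str] | None = None) -> Alignment:
        return Alignment(list(self.rows), column_labels)


class ProfileAlignResult(NamedTuple):
    score: float
    profile: Profile
    ops: str


def _apply_ops(rows: list[tuple[str, str]], ops: str, consume: str) -> list[tuple[str, str]]:
    """Project member rows through a traceback, inserting gap columns."""
    out = []
    for rid, row in rows:
        buf = []
        pos = 0
        for op in ops:
            if op == OP_DIAG or op == consume:
                buf.append(row[pos])
                pos += 1
            else:
                buf.append(GAP)
        out.append((rid, "".join(buf)))
    return out


def profile_align(
    p: Profile,
    q: Profile,
    matrix: SubstitutionMatrix,
    gaps: GapModel,
    free_ends: bool = False,
) -> ProfileAlignResult:
    """Align two profiles; only whole gap columns are inserted.

    Column-vs-column score is the average substitution score over all
    residue pairs between the columns (gaps contribute 0 to the numerator;
    the denominator is members(p) * members(q)).  Internally the DP runs on
    the integer numerators with gap penalties scaled by the same product,
    which is exactly equivalent and keeps traceback ties deterministic.
    """
    scale = p.n_members * q.n_members
    colscore = p.counts @ matrix.scores @ q.counts.T
    score, ops = affine_dp(
        colscore, gaps.gap_open * scale, gaps.gap_extend * scale, free_ends
    )
    rows = _apply_ops(p.rows, ops, OP_UP) + _apply_ops(q.rows, ops, OP_LEFT)
    return ProfileAlignResult(score / scale, Profile(rows), ops)


def pairwise_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix,
    gaps: GapModel,
    ids: tuple[str, str] = ("a", "b"),
) -> tuple[int, Alignment]:
    """Optimal global affine-gap alignment of two sequences."""
    ia = np.array([_RES_INDEX[c] for c in a], dtype=np.intp)
    ib = np.array([_RES_INDEX[c] for c in b], dtype=np.intp)
    colscore = matrix.scores[np.ix_(ia, ib)] if len(a) and len(b) else np.zeros(
        (len(a), len(b)), dtype=np.int64
    )
    score, ops = affine_dp(colscore, gaps.gap_open, gaps.gap_extend)
    rows = _apply_ops([(ids[0], a)], ops, OP_UP) + _apply_ops([(ids[1], b)], ops, OP_LEFT)
    return score, Alignment(rows)


# ---------------------------------------------------------------------------
# k-mer distances
# ---------------------------------------------------------------------------

def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """Fractional k-mer dissimilarity in [0, 1].

    d = 1 - shared / (min(len) - k + 1), where *shared* counts k-mer types
    with their minimum multiplicity in the two sequences.  k is clamped to
    the shorter sequence length when necessary, so identical sequences
    always give 0.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    k = max(1, min(k, len(a), len(b)))
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum(min(n, cb[kmer]) for kmer, n in ca.items())
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - shared / denom


_SeqLike = Union[SequenceRecord, SegmentedSequence, tuple]


def _id_and_residues(item: _SeqLike) -> tuple[str, str]:
    if isinstance(item, SegmentedSequence):
        return item.record.id, item.record.residues
    if isinstance(item, SequenceRecord):
        return item.id, item.residues
    rid, seq = item
    return rid, seq


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)


def build_distance_matrix(items: Sequence[_SeqLike], k: int = 3) -> DistanceMatrix:
    """Pairwise k-mer distances on full-length residues."""
    pairs = [_id_and_residues(it) for it in items]
    if len(pairs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(pairs)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_distance(pairs[i][1], pairs[j][1], k)
    return DistanceMatrix([rid for rid, _ in pairs], d)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Guide-tree node; leaves carry a name, internal nodes a merge height."""

    height: float
    name: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        left, right = self.children
        return left.leaf_names() + right.leaf_names()


@dataclass
class GuideTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{blen:.6g}"
            left, right = node.children
            inner = f"({render(left, node.height)},{render(right, node.height)})"
            return f"{inner}:{blen:.6g}"

        root = self.root
        if root.is_leaf:
            return f"{root.name};"
        left, right = root.children
        return f"({render(left, root.height)},{render(right, root.height)});"


def _row_argmin(row: np.ndarray, active: np.ndarray, self_idx: int) -> int:
    """Leftmost index of the minimum entry among active partners."""
    best = -1
    best_val = np.inf
    for j in range(len(row)):
        if j == self_idx or not active[j]:
            continue
        if row[j] < best_val:
            best_val = row[j]
            best = j
    return best


def upgma(dist: DistanceMatrix) -> GuideTree:
    """UPGMA with per-row minimum references (O(N^2) total).

    Merges the closest active pair at height d/2 and replaces it by a
    cluster whose distances are the size-weighted averages.  Ties break on
    the lowest (i, j) pair in row-major order, matching the naive O(N^3)
    scan, so results are identical to the reference algorithm.
    """
    n = dist.n
    if n == 1:
        return GuideTree(TreeNode(0.0, name=dist.ids[0]))
    d = dist.d.astype(float).copy()
    active = np.ones(n, dtype=bool)
    sizes = [1] * n
    nodes: list[TreeNode] = [TreeNode(0.0, name=rid) for rid in dist.ids]
    row_min = [_row_argmin(d[i], active, i) for i in range(n)]

    for _ in range(n - 1):
        # global minimum via the row references; first (lowest-i) strict win
        bi = -1
        bv = np.inf
        for i in range(n):
            if not active[i]:
                continue
            j = row_min[i]
            if j >= 0 and d[i, j] < bv:
                bv = d[i, j]
                bi = i
        i, j = bi, row_min[bi]
        a, b = (i, j) if i < j else (j, i)

        merged = TreeNode(bv / 2.0, children=(nodes[a], nodes[b]))
        sa, sb = sizes[a], sizes[b]
        for k in range(n):
            if active[k] and k not in (a, b):
                d[a, k] = d[k, a] = (sa * d[a, k] + sb * d[b, k]) / (sa + sb)
        active[b] = False
        sizes[a] = sa + sb
        nodes[a] = merged
        if active.sum() == 1:
            return GuideTree(merged)
        row_min[a] = _row_argmin(d[a], active, a)
        for k in range(n):
            if not active[k] or k == a:
                continue
            if row_min[k] in (a, b):
                row_min[k] = _row_argmin(d[k], active, k)
            elif d[k, a] < d[k, row_min[k]] or (
                d[k, a] == d[k, row_min[k]] and a < row_min[k]
            ):
                row_min[k] = a
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def progressive_align(
    items: Sequence[_SeqLike],
    tree: GuideTree,
    matrix: SubstitutionMatrix,
    gaps: GapModel,
    free_ends: bool = False,
) -> Alignment:
    """Merge profiles along the guide tree (post-order); rows follow input order.

    Accepts plain records or (id, residues) pairs; residues may be empty
    strings (they become all-gap rows), which is how empty region slots
    travel through the region-wise stage.
    """
    pairs = [_id_and_residues(it) for it in items]
    by_id = dict(pairs)
    if len(by_id) != len(pairs):
        raise ValueError("duplicate ids in progressive_align input")
    leaf_set = set(tree.leaf_names())
    if leaf_set != set(by_id):
        raise ValueError("guide-tree leaves do not match input ids")

    def recurse(node: TreeNode) -> Profile:
        if node.is_leaf:
            return Profile.from_sequence(node.name, by_id[node.name])
        left, right = node.children
        return profile_align(
            recurse(left), recurse(right), matrix, gaps, free_ends
        ).profile

    profile = recurse(tree.root)
    row_map = dict(profile.rows)
    return Alignment([(rid, row_map[rid]) for rid, _ in pairs])
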