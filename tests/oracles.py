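"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the local-alignment
scorer enumerates chains of aligned columns rather than running the
Gotoh/Smith-Waterman recursion of an alignment library, and the additive
tree generator computes leaf distances by explicit path summation.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def local_alignment_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Best local alignment score under affine gaps (length-g gap scores
    gap_open + g*gap_extend).

    Enumerates every local alignment as a chain of aligned columns
    separated by at most one deletion run and one insertion run (any
    interleaving of runs between two aligned columns scores worse under
    affine penalties, so the maximum is unaffected). Returns 0.0 when the
    empty alignment is best. Practical for sequences up to ~10 bp.
    """

    def s(x: str, y: str) -> float:
        return match if x == y else mismatch

    @lru_cache(maxsize=None)
    def end_at(i: int, j: int) -> float:
        best = s(a[i], b[j])  # alignment starting at this column
        for k in range(i):
            for l in range(j):
                dr, dq = i - k - 1, j - l - 1
                gap = 0.0
                if dr:
                    gap += gap_open + gap_extend * dr
                if dq:
                    gap += gap_open + gap_extend * dq
                best = max(best, end_at(k, l) + gap + s(a[i], b[j]))
        return best

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, end_at(i, j))
    end_at.cache_clear()
    return best


class AdditiveTree:
    """Random binary tree with positive branch lengths; distances by path
    summation. Used to test that neighbor joining recovers the topology."""

    def __init__(self, n_taxa: int, rng: np.random.Generator, min_bl: float = 0.05):
        labels = [f"t{i}" for i in range(n_taxa)]
        nodes = [(lbl,) for lbl in labels]  # leaf = (label,)
        lengths: dict[int, float] = {}

        def new_len() -> float:
            return float(min_bl + rng.uniform(0.0, 1.0))

        # random sequential agglomeration into a rooted binary shape
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            right = nodes.pop(j)
            left = nodes.pop(i)
            nodes.append((left, new_len(), right, new_len()))
        self.root = nodes[0]
        self.labels = labels

    def _leaf_dists(self, node) -> list[tuple[str, float]]:
        if len(node) == 1:
            return [(node[0], 0.0)]
        left, bl, right, br = node
        return [(l, d + bl) for l, d in self._leaf_dists(left)] + [
            (l, d + br) for l, d in self._leaf_dists(right)
        ]

    def distances(self) -> tuple[list[str], np.ndarray]:
        n = len(self.labels)
        idx = {l: i for i, l in enumerate(self.labels)}
        mat = np.zeros((n, n))

        def walk(node):
            if len(node) == 1:
                return
            left, bl, right, br = node
            for l1, d1 in self._leaf_dists(left):
                for l2, d2 in self._leaf_dists(right):
                    d = d1 + bl + d2 + br
                    mat[idx[l1], idx[l2]] = mat[idx[l2], idx[l1]] = d
            walk(left)
            walk(right)

        walk(self.root)
        return self.labels, mat

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits of the unrooted version of the tree."""
        taxa = frozenset(self.labels)
        parts: set[frozenset] = set()

        def walk(node):
            if len(node) == 1:
                return frozenset([node[0]])
            left, _, right, _ = node
            below = walk(left) | walk(right)
            other = taxa - below
            if len(below) > 1 and len(other) > 1:
                parts.add(frozenset({below, other}))
            return below

        walk(self.root)
        return parts
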