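"""Distance-based phylogeny of major ribotypes.

Major-ribotype consensus sequences are compared by p-distance or
Jukes-Cantor distance, joined into an unrooted tree by neighbor joining,
and edges are assessed by non-parametric bootstrap over alignment columns
(support as a percentage of replicates containing the bipartition).
Also provides the cross-species ribotype search and the locus-number vs
ribotype-diversity rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from ._util import as_rng
from .cluster import ClusterTable, consensus_sequence

Bipartition = frozenset  # frozenset({frozenset(side), frozenset(other side)})


def pairwise_distance(
    sequences: Sequence[tuple[str, str]],
    model: str = "p",
) -> DistanceMatrix:
    """Pairwise distances between aligned, equal-length sequences.

    ``model="p"`` gives the raw mismatch proportion over columns where
    neither sequence is gapped; ``model="jc"`` applies the Jukes-Cantor
    correction −(3/4)·ln(1 − 4p/3), with entries at p >= 0.75 flagged as
    infinite (the correction is undefined at saturation).
    """
    if model not in ("p", "jc"):
        raise ValueError("model must be 'p' or 'jc'")
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    names = [n for n, _ in sequences]
    seqs = [s.upper() for _, s in sequences]
    if len(set(map(len, seqs))) != 1:
        raise ValueError("sequences must be aligned to equal length")
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [
                (a, b) for a, b in zip(seqs[i], seqs[j]) if a != "-" and b != "-"
            ]
            if not pairs:
                raise ValueError(f"no comparable columns between {names[i]} and {names[j]}")
            p = sum(a != b for a, b in pairs) / len(pairs)
            if model == "jc":
                p = math.inf if p >= 0.75 else -0.75 * math.log1p(-4 * p / 3)
            mat[i, j] = mat[j, i] = p
    return DistanceMatrix(mat, names)


def _transfer_negative_lengths(tree: TreeNode) -> TreeNode:
    """Clamp negative branch lengths to 0, moving the deficit onto the
    sister edge so path lengths through the parent are preserved."""
    for node in tree.postorder(include_self=False):
        if node.length is not None and node.length < 0:
            for sib in node.parent.children:
                if sib is not node and sib.length is not None:
                    sib.length = max(0.0, sib.length + node.length)
            node.length = 0.0
    return tree


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (>= 3 taxa).

    Negative branch lengths produced by the NJ formulas are clamped to
    zero with the deficit transferred to the sister edge.
    """
    if matrix.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = nj(matrix, neg_as_zero=False)
    return _transfer_negative_lengths(tree)


def bipartitions(tree: TreeNode) -> set[Bipartition]:
    """Non-trivial bipartitions (internal edges) of an unrooted tree."""
    taxa = frozenset(t.name for t in tree.tips())
    parts: set[Bipartition] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) > 1 and len(other) > 1:
            parts.add(frozenset({side, other}))
    return parts


def bootstrap_support(
    sequences: Sequence[tuple[str, str]],
    n_replicates: int = 500,
    seed: int | np.random.Generator = 0,
    model: str = "p",
) -> tuple[TreeNode, dict[Bipartition, float]]:
    """Column-resampling bootstrap for the NJ tree of ``sequences``.

    Returns the tree built from the full alignment, with internal nodes
    labelled by support (percent of replicates whose NJ tree contains the
    same bipartition), plus the support map itself.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = as_rng(seed)
    ordered = sorted(sequences, key=lambda ns: ns[0])
    names = [n for n, _ in ordered]
    cols = np.array([list(s.upper()) for _, s in ordered])
    tree = neighbor_joining(pairwise_distance(ordered, model=model))
    counts: dict[Bipartition, int] = {bp: 0 for bp in bipartitions(tree)}
    n_cols = cols.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        resampled = ["".join(row) for row in cols[:, idx]]
        if all(s == resampled[0] for s in resampled):
            continue  # degenerate replicate: star tree, supports nothing
        try:
            rep = neighbor_joining(
                pairwise_distance(list(zip(names, resampled)), model=model)
            )
        except ValueError:
            continue
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    taxa = frozenset(names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        bp = frozenset({side, taxa - side})
        if bp in support:
            node.name = f"{support[bp]:.0f}"
    return tree, support


@dataclass(frozen=True)
class RibotypeMatch:
    query: str
    target_species: str
    target_profile: str
    mismatches: int
    target_count: int


def cross_species_search(
    queries: Sequence[tuple[str, str]],
    targets: Iterable[tuple[ClusterTable, "UnitTemplate"]],
    max_mismatch: int = 0,
) -> dict[str, list[RibotypeMatch]]:
    """Search other species' cluster tables for each query ribotype.

    ``queries`` are (name, consensus sequence); each target is a cluster
    table with its species template. A target cluster of ANY abundance
    (including low-copy clusters) matches when its consensus is within
    ``max_mismatch`` substitutions of the query. Species-specific panels
    give empty match lists.
    """
    results: dict[str, list[RibotypeMatch]] = {name: [] for name, _ in queries}
    for table, template in targets:
        for c in table.clusters:
            target_seq = consensus_sequence(template, c.profile)
            for name, qseq in queries:
                if len(qseq) != len(target_seq):
                    continue
                mm = sum(a != b for a, b in zip(qseq, target_seq))
                if mm <= max_mismatch:
                    results[name].append(
                        RibotypeMatch(
                            query=name,
                            target_species=table.species,
                            target_profile=c.profile.notation(),
                            mismatches=mm,
                            target_count=c.count,
                        )
                    )
    return results


def locus_diversity_summary(
    records: Sequence[tuple[str, int, int]],
) -> tuple[pd.DataFrame, float]:
    """Rank correlation between rDNA locus number and ribotype diversity.

    ``records`` are (species, n_loci, major_ribotype_count) with >= 3
    species. Returns the per-species table and the Spearman rho (midrank
    ties). No p-value is reported: these comparisons involve only a
    handful of species.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 species records")
    df = pd.DataFrame(records, columns=["species", "n_loci", "major_ribotypes"])
    rho = float(stats.spearmanr(df["n_loci"], df["major_ribotypes"]).statistic)
    return df, rho
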