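"""p-distance matrices, neighbor joining, and column bootstrap.

Distances are proportions of differing sites under pairwise deletion
(columns where either row is gapped are skipped for that pair). Trees are
built with the Saitou–Nei neighbor-joining criterion; bootstrap supports
are the percentage of column-resampled replicate trees containing each
internal bipartition of the full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import MultipleAlignment
from .tree import PhyloTree, TreeNode

GAP_BYTE = ord("-")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    site_counts: np.ndarray | None = None  # usable sites per pair

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")


def _alignment_bytes(aln: MultipleAlignment) -> np.ndarray:
    return np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln.rows), aln.columns)


def p_distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gapped columns."""
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 aligned rows")
    A = _alignment_bytes(aln)
    valid = A != GAP_BYTE
    both = valid[:, None, :] & valid[None, :, :]
    counts = both.sum(axis=2)
    mism = ((A[:, None, :] != A[None, :, :]) & both).sum(axis=2)
    off = ~np.eye(len(aln.ids), dtype=bool)
    if np.any(counts[off] == 0):
        i, j = np.argwhere((counts == 0) & off)[0]
        raise ValueError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(counts > 0, mism / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(aln.ids), d, counts)


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The minimum-Q pair is chosen in row-major (lexicographic) order among
    ties; negative branch lengths are clamped to zero with the deficit
    moved to the sister branch so the pair's summed length is preserved.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dist.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(label=i) for i in dist.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qvals = Q[iu]
        k = int(np.argmin(qvals))  # first minimum = lexicographic pair
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = D[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]
        newd = (D[i, :] + D[j, :] - dij) / 2.0
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = newd[keep]
        D2[:-1, -1] = newd[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]
    # Final three nodes: three-point formulas around a trifurcating root.
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max((dab + dac - dbc) / 2.0, 0.0)
    b.length = max((dab + dbc - dac) / 2.0, 0.0)
    c.length = max((dac + dbc - dab) / 2.0, 0.0)
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root)


def bootstrap_supports(
    aln: MultipleAlignment, n_replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap supports.

    Replicate r resamples columns with a counter-derived stream
    ``default_rng([seed, r])`` so runs are reproducible and independent of
    evaluation order.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    full_tree = neighbor_joining(p_distance_matrix(aln))
    target = full_tree.bipartitions()
    counts = {bp: 0 for bp in target}
    A = _alignment_bytes(aln)
    L = aln.columns
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, L, size=L)
        rep_aln = MultipleAlignment(
            ids=list(aln.ids),
            rows=[
                bytes(row).decode("ascii") for row in A[:, cols]
            ],
        )
        rep_tree = neighbor_joining(p_distance_matrix(rep_aln))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    _attach_supports(full_tree, support)
    return full_tree


def _attach_supports(tree: PhyloTree, support: dict[frozenset, float]) -> None:
    all_leaves = frozenset(tree.leaf_labels())
    ref = min(all_leaves)

    def walk(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        leafset = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 1 < len(leafset) < len(all_leaves) - 1:
            side = leafset if ref not in leafset else all_leaves - leafset
            if side in support:
                node.support = support[side]
        return leafset

    walk(tree.root)
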