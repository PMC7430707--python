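"""Minimal phylogenetic tree container.

Trees are stored rooted at a (usually trifurcating) root node purely for
serialization; the topology they represent is unrooted. Bootstrap supports
live on internal nodes and are emitted as internal node labels in Newick,
the convention MEGA and most viewers expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TreeNode:
    label: str | None = None  # leaf label; internal nodes are unlabeled
    length: float = 0.0  # branch length to parent
    support: float | None = None  # bootstrap percentage, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    def __init__(self, root: TreeNode) -> None:
        self.root = root

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def _adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            adj.setdefault(id(node), [])
            for child in node.children:
                adj.setdefault(id(child), [])
                adj[id(node)].append((id(child), child.length))
                adj[id(child)].append((id(node), child.length))
                stack.append(child)
        return adj

    def distances_from(self, leaf_label: str) -> dict[str, float]:
        """Path lengths from one leaf to every other leaf."""
        nodes: dict[int, TreeNode] = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            nodes[id(node)] = node
            stack.extend(node.children)
        start = next(
            (n for n in nodes.values() if n.is_leaf and n.label == leaf_label),
            None,
        )
        if start is None:
            raise KeyError(f"leaf {leaf_label!r} not in tree")
        adj = self._adjacency()
        dist = {id(start): 0.0}
        frontier = [id(start)]
        while frontier:
            u = frontier.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    frontier.append(v)
        return {
            nodes[k].label: d
            for k, d in dist.items()
            if nodes[k].is_leaf and k != id(start)
        }

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each canonicalized as the leaf set
        on the child side of the edge, re-canonicalized to exclude a fixed
        reference taxon so the two sides of an edge map to one key."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def clade(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            leafset = frozenset().union(*(clade(c) for c in node.children))
            if node is not self.root and 1 < len(leafset) < len(all_leaves) - 1:
                side = leafset if ref not in leafset else all_leaves - leafset
                out.add(side)
            return leafset

        clade(self.root)
        return out

    def _newick_node(self, node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.label}:{node.length:.10g}"
        inner = ",".join(self._newick_node(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:.10g}"
        return f"({inner}){label}:{node.length:.10g}"

    def to_newick(self) -> str:
        inner = ",".join(self._newick_node(c) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:.10g}"
        return f"({inner}){label};"
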