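"""Rooted phylogenetic trees with branch lengths.

Trees are parsed and serialised with dendropy; the in-memory structure is a
small node/pointer representation tailored to the likelihood and counting
engines, where every branch is addressed by its child node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    pass


@dataclass(eq=False)
class Node:
    """A tree node; ``length`` is the length of the edge to the parent."""

    id: int = -1
    name: Optional[str] = None
    length: float = 0.0
    parent: Optional["Node"] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "internal"
        return f"<Node {self.id} {kind} {self.name or ''}>"


class PhyloTree:
    """A rooted tree whose branches are identified by their child node.

    Node ids are assigned in postorder and are stable for the lifetime of the
    object; they are re-assigned by structural operations such as pruning.
    """

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls._from_dendropy(dt)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        dt = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        def convert(dnode) -> Node:
            node = Node()
            if dnode.taxon is not None:
                node.name = dnode.taxon.label
            elif dnode.label:
                node.name = dnode.label
            node.length = float(dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                cn = convert(child)
                cn.parent = node
                node.children.append(cn)
            return node

        root = convert(dt.seed_node)
        root.length = 0.0
        return cls(root)

    def _reindex(self) -> None:
        self._postorder: list[Node] = []

        def walk(node: Node) -> None:
            for child in node.children:
                walk(child)
            node.id = len(self._postorder)
            self._postorder.append(node)

        walk(self.root)
        seen: set[str] = set()
        for leaf in self.leaves():
            if leaf.name is None:
                raise TreeError("leaf without a taxon name")
            if leaf.name in seen:
                raise TreeError(f"duplicate taxon name {leaf.name!r}")
            seen.add(leaf.name)

    # -- traversal and lookup ---------------------------------------------

    def postorder(self) -> Iterator[Node]:
        return iter(self._postorder)

    def preorder(self) -> Iterator[Node]:
        return reversed(self._postorder)

    def leaves(self) -> list[Node]:
        return [n for n in self._postorder if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def node(self, node_id: int) -> Node:
        return self._postorder[node_id]

    def find(self, name: str) -> Node:
        for n in self._postorder:
            if n.name == name:
                return n
        raise TreeError(f"no node named {name!r} in tree")

    def mrca(self, taxa: Iterable[str]) -> Node:
        """Most recent common ancestor of a set of leaf taxa."""
        taxa = set(taxa)
        missing = taxa - set(self.taxa)
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        counts: dict[int, int] = {}
        for node in self.postorder():
            if node.is_leaf:
                counts[node.id] = 1 if node.name in taxa else 0
            else:
                counts[node.id] = sum(counts[c.id] for c in node.children)
            if counts[node.id] == len(taxa):
                return node
        raise TreeError("mrca search failed")  # pragma: no cover

    def clade_taxa(self, node: Node) -> frozenset:
        """Leaf taxa subtended by ``node``."""
        if node.is_leaf:
            return frozenset([node.name])
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def is_ancestor(self, anc: Node, node: Node) -> bool:
        """True if ``anc`` lies on the root-to-``node`` path (inclusive)."""
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    def depth(self, node: Node) -> int:
        d = 0
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    def path_length(self, taxon_a: str, taxon_b: str) -> float:
        a, b = self.find(taxon_a), self.find(taxon_b)
        anc_a = {}
        d = 0.0
        n = a
        while n is not None:
            anc_a[id(n)] = d
            d += n.length
            n = n.parent
        d = 0.0
        n = b
        while n is not None:
            if id(n) in anc_a:
                return d + anc_a[id(n)]
            d += n.length
            n = n.parent
        raise TreeError("disconnected nodes")  # pragma: no cover

    # -- structural operations --------------------------------------------

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            new = Node(name=node.name, length=node.length)
            for child in node.children:
                cn = dup(child)
                cn.parent = new
                new.children.append(cn)
            return new

        return PhyloTree(dup(self.root))

    def prune_to(self, taxa: Iterable[str]) -> "PhyloTree":
        """Restrict to ``taxa``, collapsing unifurcations by summing lengths.

        Path lengths between every pair of retained leaves are preserved.
        """
        keep = set(taxa)
        missing = keep - set(self.taxa)
        if missing:
            raise TreeError(f"cannot prune to unknown taxa: {sorted(missing)}")
        if len(keep) < 2:
            raise TreeError("pruning must retain at least two taxa")

        def build(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.name in keep:
                    return Node(name=node.name, length=node.length)
                return None
            kids = [c for c in (build(ch) for ch in node.children) if c is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            new = Node(name=node.name, length=node.length)
            for k in kids:
                k.parent = new
                new.children.append(k)
            return new

        root = build(self.root)
        root.length = 0.0
        root.parent = None
        return PhyloTree(root)

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner}){node.name or ''}"
            if node.parent is None:
                return label
            return f"{label}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def n_branches(self) -> int:
        return len(self._postorder) - 1

    # -- branch resolution -------------------------------------------------

    def resolve_branch(self, spec) -> Node:
        """Resolve a branch specifier to its child node.

        Accepts a :class:`Node`, an integer node id, a node/taxon name, or
        ``"mrca:taxonA+taxonB+..."``.
        """
        if isinstance(spec, Node):
            return spec
        if isinstance(spec, int):
            return self.node(spec)
        if isinstance(spec, str) and spec.startswith("mrca:"):
            return self.mrca(spec[5:].split("+"))
        return self.find(spec)
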