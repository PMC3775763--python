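"""Lightweight phylogenetic tree structure shared by the whole pipeline.

A :class:`Tree` is a rooted node structure; unrooted trees are represented
with a trifurcating root.  Newick text is parsed with dendropy and converted;
writing is direct recursion.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional

import dendropy

__all__ = ["Node", "Tree", "bipartitions", "rf_distance", "topologies_equal"]


class Node:
    __slots__ = ("name", "length", "children", "parent", "support", "age")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length  # length of the edge above this node
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.support: Optional[float] = None
        self.age: Optional[float] = None  # used by dated/ultrametric trees

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length:.4g}, k={len(self.children)})"


class Tree:
    """Rooted (or unrooted-with-trifurcating-root) leaf-labelled tree."""

    def __init__(self, root: Node):
        self.root = root

    # ---------------------------------------------------------------- trav
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def mrca(self, names: set[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        want = set(names)
        below: dict[Node, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n] = {n.name}
            else:
                s: set[str] = set()
                for c in n.children:
                    s |= below[c]
                below[n] = s
            if want <= below[n]:
                return n
        raise KeyError(f"taxa {sorted(want)} not all present in tree")

    # ---------------------------------------------------------------- copy
    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.support = n.support
            m.age = n.age
            for c in n.children:
                m.add_child(rec(c))
            return m

        return Tree(rec(self.root))

    # ------------------------------------------------------------- newick
    def to_newick(self, lengths: bool = True, support: bool = False) -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                s = n.name or ""
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")"
                if support and n.support is not None:
                    s += format(n.support, "g")
                elif n.name:
                    s += n.name
            if lengths and n.parent is not None:
                s += f":{n.length:.10g}"
            return s

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dt = dendropy.Tree.get(file=io.StringIO(text), schema="newick",
                               preserve_underscores=True)

        def rec(dn) -> Node:
            name = dn.taxon.label if dn.taxon is not None else dn.label
            n = Node(name, dn.edge.length if dn.edge.length is not None else 0.0)
            for dc in dn.child_nodes():
                n.add_child(rec(dc))
            return n

        return cls(rec(dt.seed_node))

    # ------------------------------------------------------------ rooting
    def unroot(self) -> "Tree":
        """Collapse a bifurcating root so the root becomes trifurcating."""
        t = self.copy()
        while len(t.root.children) == 2 and not all(c.is_leaf for c in t.root.children):
            a, b = t.root.children
            keep, absorb = (a, b) if not a.is_leaf else (b, a)
            # absorb `keep` (internal) into the root
            t.root.children.remove(keep)
            for c in keep.children:
                c.length += 0.0
                t.root.add_child(c)
            absorb.length += keep.length
        return t

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> "Tree":
        """Return a new tree rooted on the edge above ``child``.

        ``fraction`` is the portion of the edge assigned to ``child``'s side.
        """
        # work on a copy: locate the corresponding node by identity path
        path = []
        n = child
        while n.parent is not None:
            path.append(n.parent.children.index(n))
            n = n.parent
        t = self.copy()
        node = t.root
        for idx in reversed(path):
            node = node.children[idx]

        old_parent = node.parent
        if old_parent is None:
            raise ValueError("cannot reroot on the root's (non-existent) edge")
        new_root = Node()
        elen = node.length
        old_parent.children.remove(node)
        node.parent = None
        node.length = elen * fraction
        new_root.add_child(node)

        # invert the path from old_parent up to the old root
        carry_len = elen * (1.0 - fraction)
        cur = old_parent
        prev = new_root
        while cur is not None:
            nxt = cur.parent
            nxt_len = cur.length
            if nxt is not None:
                nxt.children.remove(cur)
            cur.parent = None
            cur.length = carry_len
            prev.add_child(cur)
            prev = cur
            carry_len = nxt_len
            cur = nxt
        # the old root may now have a single child: splice it out
        t2 = Tree(new_root)
        t2._suppress_unifurcations()
        return t2

    def _suppress_unifurcations(self) -> None:
        for n in list(self.postorder()):
            if n.parent is not None and len(n.children) == 1:
                (c,) = n.children
                c.length += n.length
                p = n.parent
                i = p.children.index(n)
                p.children[i] = c
                c.parent = p
        if len(self.root.children) == 1 and not self.root.children[0].is_leaf:
            c = self.root.children[0]
            c.parent = None
            c.length = 0.0
            self.root = c


# ------------------------------------------------------------------ splits
def bipartitions(tree: Tree) -> set[frozenset]:
    """Non-trivial bipartitions of an (un)rooted tree, as canonical leaf sets.

    Each internal edge induces a split; the side NOT containing the
    lexicographically smallest leaf is the canonical representative, making
    the set rooting-invariant.
    """
    names = sorted(tree.leaf_names())
    if len(names) != len(set(names)):
        raise ValueError("leaf labels are not unique")
    ref = names[0]
    all_set = frozenset(names)
    out: set[frozenset] = set()
    below: dict[Node, frozenset] = {}
    for n in tree.postorder():
        if n.is_leaf:
            below[n] = frozenset([n.name])
        else:
            s = frozenset().union(*(below[c] for c in n.children))
            below[n] = s
            if n.parent is None:
                continue
            side = s if ref not in s else all_set - s
            if 2 <= len(side) <= len(names) - 2:
                out.add(side)
    return out


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: symmetric difference of internal splits."""
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}")
    return len(bipartitions(t1) ^ bipartitions(t2))


def topologies_equal(t1: Tree, t2: Tree) -> bool:
    return rf_distance(t1, t2) == 0
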