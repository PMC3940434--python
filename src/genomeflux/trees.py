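"""Phylogenetic tree container with per-branch class labels.

The analyses in this package hang quantities off *branches* (gain/loss
flux, dN/dS ratio classes), so the tree container keeps, for every edge,
a branch length in expected substitutions per site and a free-form class
label (e.g. ``"anc1"`` .. ``"anc9"`` for the labeled ancestral branches,
``"syn"`` for the Synechococcus side, clade tags elsewhere).  Newick
round-trips encode the label as a ``[&class=...]`` comment on the node
below the edge.
"""

from __future__ import annotations

import io
import itertools
import re
from dataclasses import dataclass, field

__all__ = ["Node", "LabeledTree"]


@dataclass
class Node:
    id: int
    name: str | None = None
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    length: float = 0.0  # length of the edge above this node
    label: str | None = None  # class label of the edge above this node

    @property
    def is_leaf(self) -> bool:
        return not self.children


class LabeledTree:
    """Rooted (or trifurcating-root "unrooted") tree with labeled edges.

    Every node except the root carries the length and class label of the
    edge connecting it to its parent.  A tree is *rooted* when the root
    has exactly two children; a trifurcating root represents an unrooted
    binary tree.
    """

    def __init__(self) -> None:
        self.nodes: dict[int, Node] = {}
        self.root: int | None = None
        self._next_id = 0

    # -- construction -------------------------------------------------

    def add_node(
        self,
        name: str | None = None,
        parent: int | None = None,
        length: float = 0.0,
        label: str | None = None,
    ) -> int:
        if length < 0:
            raise ValueError("branch lengths must be non-negative")
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = Node(nid, name=name, parent=parent, length=length, label=label)
        if parent is None:
            if self.root is not None:
                raise ValueError("tree already has a root")
            self.root = nid
        else:
            self.nodes[parent].children.append(nid)
        return nid

    def copy(self) -> "LabeledTree":
        t = LabeledTree()
        t._next_id = self._next_id
        t.root = self.root
        for nid, n in self.nodes.items():
            t.nodes[nid] = Node(nid, n.name, n.parent, list(n.children), n.length, n.label)
        return t

    # -- queries -------------------------------------------------------

    @property
    def is_rooted(self) -> bool:
        return self.root is not None and len(self.nodes[self.root].children) == 2

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.nodes[self.root], False)]
        while stack:
            node, done = stack.pop()
            if done or node.is_leaf:
                out.append(node)
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((self.nodes[c], False))
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.nodes[self.root]]
        while stack:
            node = stack.pop()
            out.append(node)
            for c in reversed(node.children):
                stack.append(self.nodes[c])
        return out

    def edges(self) -> list[Node]:
        """Every non-root node stands for the edge above it."""
        return [n for n in self.postorder() if n.parent is not None]

    def find(self, name: str) -> Node:
        for n in self.nodes.values():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    def branch_labels(self) -> list[str]:
        return [e.label for e in self.edges() if e.label is not None]

    def path_to_root(self, nid: int) -> list[Node]:
        out = []
        while nid is not None:
            out.append(self.nodes[nid])
            nid = self.nodes[nid].parent
        return out

    # -- rerooting -----------------------------------------------------

    def rooted_at_outgroup(self, outgroup: str, stem_fraction: float = 0.5) -> "LabeledTree":
        """Return a copy rooted on the edge above the named leaf.

        The outgroup leaf's edge is split; ``stem_fraction`` of its length
        goes to the outgroup side.  If the leaf's current parent is not
        the root, parent pointers along the path are reversed first.
        """
        t = self.copy()
        og = t.find(outgroup)
        if not og.is_leaf:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf")
        # make og's parent the apex: reverse parent pointers along the path
        # to the old root, moving each edge's (length, label) to its new child
        path = t.path_to_root(og.parent)
        edge_data = [(n.length, n.label) for n in path[:-1]]  # edge above path[i]
        for i in range(len(path) - 1):
            below, above = path[i], path[i + 1]
            above.children.remove(below.id)
            below.children.append(above.id)
            above.parent = below.id
            above.length, above.label = edge_data[i]
        apex = path[0]
        apex.parent = None
        apex.length, apex.label = 0.0, None
        # lengths were shifted: re-assign correctly (edge between path[i] and
        # path[i+1] keeps its original length, now stored on path[i+1]).
        # Build new root splitting the outgroup edge.
        apex.children.remove(og.id)
        root_id = t._next_id
        t._next_id += 1
        half = og.length * stem_fraction
        root = Node(root_id, parent=None, children=[og.id, apex.id])
        t.nodes[root_id] = root
        og.parent = root_id
        og.length = og.length - half
        apex.parent = root_id
        apex.length = half
        apex.label = og.label
        t.root = root_id
        t._drop_unary()
        return t

    def _drop_unary(self) -> None:
        """Collapse internal nodes with a single child (merging lengths)."""
        changed = True
        while changed:
            changed = False
            for n in list(self.nodes.values()):
                if n.parent is not None and len(n.children) == 1:
                    child = self.nodes[n.children[0]]
                    parent = self.nodes[n.parent]
                    child.length += n.length
                    child.parent = parent.id
                    parent.children[parent.children.index(n.id)] = child.id
                    del self.nodes[n.id]
                    changed = True

    # -- newick --------------------------------------------------------

    def to_newick(self, labels: bool = True) -> str:
        def fmt(nid: int) -> str:
            n = self.nodes[nid]
            if n.is_leaf:
                s = n.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.name:
                    s += n.name
            if n.parent is not None:
                if labels and n.label:
                    s += f"[&class={n.label}]"
                s += f":{n.length:g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "LabeledTree":
        """Parse Newick with optional ``[&class=...]`` edge comments."""
        text = text.strip().rstrip(";")
        t = cls()
        pos = 0

        def parse(parent: int | None) -> int:
            nonlocal pos
            if text[pos] == "(":
                nid = t.add_node(parent=parent)
                pos += 1
                while True:
                    parse(nid)
                    if text[pos] == ",":
                        pos += 1
                    else:
                        break
                assert text[pos] == ")", f"malformed newick at {pos}"
                pos += 1
            else:
                nid = t.add_node(parent=parent)
            m = re.match(r"[^,():\[\]]*", text[pos:])
            name = m.group(0)
            pos += len(name)
            if name:
                t.nodes[nid].name = name
            if pos < len(text) and text[pos] == "[":
                end = text.index("]", pos)
                comment = text[pos + 1 : end]
                cm = re.search(r"class=([^,\]]+)", comment)
                if cm:
                    t.nodes[nid].label = cm.group(1)
                pos = end + 1
            if pos < len(text) and text[pos] == ":":
                pos += 1
                m = re.match(r"[0-9.eE+-]+", text[pos:])
                t.nodes[nid].length = float(m.group(0))
                pos += len(m.group(0))
            return nid

        parse(None)
        return t

    def __repr__(self) -> str:  # pragma: no cover
        return f"<LabeledTree {len(self.leaves())} leaves, rooted={self.is_rooted}>"
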