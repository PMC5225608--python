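"""Phylogenies with branch lengths and branch-class labels.

Trees are rooted node structures with an edge partition into integer branch
classes (0 = background by convention, 1 = foreground).  Classes can come
from PAML-style ``#<int>`` marks in the Newick string or be painted onto a
named clade (optionally including its stem edge) afterwards.
"""

from __future__ import annotations

from typing import Sequence


class NewickError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "cls", "parent", "children", "index")

    def __init__(
        self,
        name: str = "",
        length: float = 0.0,
        cls: int = 0,
    ) -> None:
        self.name = name
        self.length = length
        self.cls = cls
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.index: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "internal"
        return f"<Node {self.name or self.index} ({kind}) t={self.length:g} #{self.cls}>"


class Phylogeny:
    """A rooted tree; branch classes partition the edges."""

    def __init__(self, root: Node, class_names: dict[int, str] | None = None):
        self.root = root
        self.class_names = dict(class_names or {0: "background", 1: "foreground"})
        self._index()

    # -- structure ---------------------------------------------------------
    def _index(self) -> None:
        self._postorder: list[Node] = []

        def walk(node: Node) -> None:
            for child in node.children:
                walk(child)
            self._postorder.append(node)

        walk(self.root)
        for i, node in enumerate(self._postorder):
            node.index = i
        leaves = [n for n in self._postorder if n.is_leaf]
        names = [n.name for n in leaves]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise NewickError(f"duplicate leaf name '{dup}'")
        self._leaf_map = {n.name: n for n in leaves}
        k = 0
        for n in self._postorder:
            if not n.is_leaf and not n.name:
                n.name = f"anc_{k}"
                k += 1
        for n in self._postorder:
            if n is not self.root and n.length < 0:
                raise NewickError(
                    f"negative branch length on edge above '{n.name}'"
                )

    def postorder(self) -> list[Node]:
        return list(self._postorder)

    def leaves(self) -> list[Node]:
        return [n for n in self._postorder if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Every non-root node stands for the edge above it."""
        return [n for n in self._postorder if n is not self.root]

    def node(self, name: str) -> Node:
        for n in self._postorder:
            if n.name == name:
                return n
        raise KeyError(f"no node named '{name}'")

    @property
    def n_classes(self) -> int:
        return max((e.cls for e in self.edges()), default=0) + 1

    def mrca(self, leaf_names: Sequence[str]) -> Node:
        target = set(leaf_names)
        missing = target - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        below: dict[Node, set[str]] = {}
        for n in self._postorder:
            if n.is_leaf:
                below[n] = {n.name}
            else:
                below[n] = set().union(*(below[c] for c in n.children))
        for n in self._postorder:  # postorder => smallest covering node first
            if target <= below[n]:
                return n
        raise AssertionError("unreachable")

    # -- branch classes ----------------------------------------------------
    def mark_clade(
        self,
        leaf_names: Sequence[str],
        cls: int,
        *,
        include_stem: bool = True,
        name: str | None = None,
    ) -> None:
        """Paint every edge inside the clade spanned by ``leaf_names``.

        ``include_stem`` also paints the edge subtending the clade's MRCA
        (the "stem" or ancestral branch).
        """
        anc = self.mrca(leaf_names)

        def paint(node: Node) -> None:
            for child in node.children:
                child.cls = cls
                paint(child)

        paint(anc)
        if include_stem and anc is not self.root:
            anc.cls = cls
        if name is not None:
            self.class_names[cls] = name

    # -- copies and restructuring ------------------------------------------
    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.cls)
            for child in node.children:
                new.add(clone(child))
            return new

        return Phylogeny(clone(self.root), self.class_names)

    def subtree(self, node_name: str) -> "Phylogeny":
        src = self.node(node_name)

        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.cls)
            for child in node.children:
                new.add(clone(child))
            return new

        root = clone(src)
        root.length = 0.0
        return Phylogeny(root, self.class_names)

    def rerooted(self, node_name: str) -> "Phylogeny":
        """Re-root at an existing internal node (reversible-model use).

        A former root left with a single child is collapsed and its two
        incident branch lengths merged, so the unrooted topology and total
        length are preserved.
        """
        target = self.node(node_name)
        if target.is_leaf:
            raise ValueError("cannot re-root at a leaf")
        if target is self.root:
            return self.copy()
        # undirected adjacency: (neighbor, length-of-connecting-edge, cls)
        adj: dict[Node, list[tuple[Node, float, int]]] = {}
        for n in self._postorder:
            adj.setdefault(n, [])
            for c in n.children:
                adj[n].append((c, c.length, c.cls))
                adj.setdefault(c, []).append((n, c.length, c.cls))

        def build(node: Node, came_from: Node | None) -> Node:
            new = Node(node.name, 0.0, 0)
            for nbr, length, cls in adj[node]:
                if nbr is came_from:
                    continue
                child = build(nbr, node)
                child.length = length
                child.cls = cls
                new.add(child)
            return new

        root = build(target, None)

        # collapse any internal node of out-degree 1 (the old root)
        def collapse(node: Node) -> None:
            for child in list(node.children):
                collapse(child)
            for child in list(node.children):
                if not child.is_leaf and len(child.children) == 1:
                    (grand,) = child.children
                    grand.length += child.length
                    grand.parent = node
                    node.children[node.children.index(child)] = grand

        collapse(root)
        return Phylogeny(root, self.class_names)

    # -- serialization -----------------------------------------------------
    def to_newick(self, *, marks: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.name.startswith("anc_") else node.name
                body = f"({inner}){label}"
            if node is self.root:
                return body
            mark = f" #{node.cls}" if (marks and node.cls != 0) else ""
            return f"{body}:{node.length:g}{mark}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {len(self.leaves())} leaves>"


def parse_newick_labelled(text: str) -> Phylogeny:
    """Parse Newick with optional PAML-style ``#<int>`` branch-class marks.

    Marks may follow a branch length (``:0.05 #1``) or a node label.  Errors
    report the character position at which parsing failed.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("missing terminating ';'")
    s = s[:-1]
    pos = 0
    n = len(s)

    def error(msg: str) -> NewickError:
        return NewickError(f"{msg} at position {pos}")

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and s[pos].isspace():
            pos += 1

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < n and s[pos] not in "():,;#" and not s[pos].isspace():
            pos += 1
        return s[start:pos]

    def read_suffix(node: Node) -> None:
        """Optional :length and #class, in either order after the label."""
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < n and (s[pos] in "+-.eE" or s[pos].isdigit()):
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise error("malformed branch length")
        skip_ws()
        if pos < n and s[pos] == "#":
            pos += 1
            start = pos
            while pos < n and s[pos].isdigit():
                pos += 1
            if start == pos:
                raise error("expected integer branch class after '#'")
            node.cls = int(s[start:pos])
            skip_ws()

    def read_clade() -> Node:
        nonlocal pos
        skip_ws()
        if pos >= n:
            raise error("unexpected end of input")
        if s[pos] == "(":
            pos += 1
            node = Node()
            while True:
                node.add(read_clade())
                skip_ws()
                if pos >= n:
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character '{s[pos]}'")
            node.name = read_label()
            read_suffix(node)
            return node
        name = read_label()
        if not name:
            raise error("expected a leaf name")
        node = Node(name)
        read_suffix(node)
        return node

    root = read_clade()
    skip_ws()
    if pos != n:
        raise NewickError(f"trailing characters at position {pos}")
    return Phylogeny(root)


def read_clade_tsv(path, tree: Phylogeny) -> dict[str, list[str]]:
    """Sidecar clade file: ``clade<TAB>leaf`` rows; ``<clade>.stem`` rows
    mark the stem edge of an already-defined clade.

    Applies classes to ``tree`` in file order: the first clade gets class 1,
    the next class 2, and so on; returns the clade membership map.
    """
    clades: dict[str, list[str]] = {}
    stems: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'clade<TAB>leaf'")
            clade, member = parts
            if member == "stem" or member.endswith(".stem"):
                stems.add(clade)
            else:
                clades.setdefault(clade, []).append(member)
    for i, (clade, members) in enumerate(clades.items(), start=1):
        tree.mark_clade(members, i, include_stem=clade in stems, name=clade)
    return clades
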