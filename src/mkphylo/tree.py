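"""Phylogenetic tree structure, Newick I/O and bipartition algebra.

Trees are stored rooted (parent/child links) but all split-based
operations — Robinson–Foulds distance, consensus, support collapsing,
resolution — are defined on the unrooted topology, which is the scale on
which tree-to-tree comparisons in this package are made.  Support values
are fractions in [0, 1] attached to internal nodes; Newick internal-node
labels greater than 1 are interpreted as bootstrap percentages and
divided by 100 on input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "Tree",
    "TreeNode",
    "Bipartition",
    "NewickError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "read_tree_list",
    "write_tree_list",
    "bipartitions",
    "rf_distance",
    "majority_rule_consensus",
    "collapse_by_support",
    "resolution",
]


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character offset {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    """Structurally invalid tree or incompatible tree pair."""


class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None,
                 support: Optional[float] = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.name or ''} {kind}>"


class Tree:
    """Rooted container for an (operationally unrooted) phylogeny."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None for n in names):
            raise TreeValidationError("every leaf must be labelled")
        dupes = [n for n, c in Counter(names).items() if c > 1]
        if dupes:
            raise TreeValidationError(f"duplicate taxon labels: {sorted(dupes)}")
        for node in self.preorder():
            if node.children and len(node.children) < 2:
                raise TreeValidationError("internal node with a single child")

    # -- traversal ----------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> Iterator[TreeNode]:
        return (n for n in self.preorder() if n.is_leaf)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())

    def copy(self) -> "Tree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree with {len(self.taxa)} taxa>"


@dataclass(frozen=True)
class Bipartition:
    """Canonical non-trivial split of the taxon set.

    ``member_set`` is the side of the split that does not contain the
    reference taxon (the first taxon in sorted order), so equality is
    plain set equality.
    """

    member_set: frozenset[str]
    universe: frozenset[str]

    @classmethod
    def from_leafset(cls, leafset: Iterable[str], universe: Iterable[str]) -> "Bipartition":
        universe = frozenset(universe)
        leafset = frozenset(leafset)
        ref = min(universe)
        if ref in leafset:
            leafset = universe - leafset
        if not 2 <= len(leafset) <= len(universe) - 2:
            raise TreeValidationError("trivial split cannot form a Bipartition")
        return cls(leafset, universe)

    def __hash__(self) -> int:
        return hash(self.member_set)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.member_set == other.member_set and self.universe == other.universe


# ---------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------

_LABEL_END = set("(),:;[]'\t\n ")


def _read_label(text: str, i: int) -> tuple[str, int]:
    if i < len(text) and text[i] == "'":
        j = text.find("'", i + 1)
        if j < 0:
            raise NewickError("unterminated quoted label", i)
        return text[i + 1:j], j + 1
    j = i
    while j < len(text) and text[j] not in _LABEL_END:
        j += 1
    return text[i:j], j


def _maybe_support(label: str) -> Optional[float]:
    try:
        value = float(label)
    except ValueError:
        return None
    if value < 0:
        return None
    # bootstrap convention: percentages for values above 1
    return value / 100.0 if value > 1 else value


def parse_newick(text: str) -> Tree:
    """Parse one Newick string into a :class:`Tree`.

    Numeric internal-node labels are read as support values; values
    above 1 are treated as percentages and divided by 100.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty Newick string", 0)
    pos = 0

    def skip_ws(i: int) -> int:
        while i < len(s) and s[i] in " \t\n":
            i += 1
        return i

    def parse_clade(i: int) -> tuple[TreeNode, int]:
        i = skip_ws(i)
        node = TreeNode()
        if i < len(s) and s[i] == "(":
            i += 1
            while True:
                child, i = parse_clade(i)
                node.add_child(child)
                i = skip_ws(i)
                if i >= len(s):
                    raise NewickError("unexpected end inside clade", i)
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                raise NewickError(f"expected ',' or ')', found {s[i]!r}", i)
            label, i = _read_label(s, skip_ws(i))
            if label:
                support = _maybe_support(label)
                if support is None:
                    node.name = label
                else:
                    node.support = support
        else:
            label, i = _read_label(s, i)
            if not label:
                raise NewickError("expected a taxon label", i)
            node.name = label
        i = skip_ws(i)
        if i < len(s) and s[i] == ":":
            num, j = _read_label(s, skip_ws(i + 1))
            try:
                node.length = float(num)
            except ValueError:
                raise NewickError(f"invalid branch length {num!r}", i + 1) from None
            i = j
        return node, i

    root, pos = parse_clade(pos)
    pos = skip_ws(pos)
    if pos >= len(s) or s[pos] != ";":
        raise NewickError("expected terminating ';'", pos)
    if skip_ws(pos + 1) != len(s):
        raise NewickError("trailing characters after ';'", pos + 1)
    return Tree(root)


def _format_node(node: TreeNode, lengths: bool, supports: bool) -> str:
    if node.is_leaf:
        out = node.name or ""
    else:
        inner = ",".join(_format_node(c, lengths, supports) for c in node.children)
        out = f"({inner})"
        if supports and node.support is not None:
            out += f"{node.support:g}"
        elif node.name:
            out += node.name
    if lengths and node.length is not None:
        out += f":{node.length:g}"
    return out


def write_newick(tree: Tree, lengths: bool = True, supports: bool = True) -> str:
    return _format_node(tree.root, lengths, supports) + ";"


def read_tree_list(path) -> list[Tree]:
    """Read a trees file with one Newick string per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_tree_list(trees: Sequence[Tree], path, lengths: bool = True,
                    supports: bool = True) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t, lengths=lengths, supports=supports) + "\n")


# ---------------------------------------------------------------------
# Bipartition algebra
# ---------------------------------------------------------------------

def _leafsets(tree: Tree) -> dict[TreeNode, frozenset[str]]:
    sets: dict[TreeNode, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[node] = frozenset([node.name])
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= sets[child]
            sets[node] = frozenset(acc)
    return sets


def bipartitions(tree: Tree) -> set[Bipartition]:
    """Non-trivial splits induced by the internal edges of the unrooted topology.

    Trees with fewer than 4 taxa have no non-trivial splits and yield the
    empty set.  A fully resolved binary tree on n taxa yields n - 3 splits.
    """
    universe = tree.taxa
    if len(universe) < 4:
        return set()
    sets = _leafsets(tree)
    out: set[Bipartition] = set()
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        leafset = sets[node]
        if 2 <= len(leafset) <= len(universe) - 2:
            out.add(Bipartition.from_leafset(leafset, universe))
    return out


def _check_same_taxa(t1: Tree, t2: Tree) -> None:
    a, b = t1.taxa, t2.taxa
    if a != b:
        raise TreeValidationError(
            f"taxon sets differ: only in first {sorted(a - b)}, only in second {sorted(b - a)}"
        )


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets."""
    _check_same_taxa(t1, t2)
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


# ---------------------------------------------------------------------
# Consensus, collapsing, resolution
# ---------------------------------------------------------------------

def majority_rule_consensus(trees: Sequence[Tree], threshold: float = 0.5) -> Tree:
    """Majority-rule consensus: exactly the splits with frequency strictly
    above ``threshold``, annotated with that frequency as node support.

    Strict comparison with threshold >= 0.5 guarantees all retained splits
    are mutually compatible, so the consensus is well defined without
    tie-breaking.
    """
    if not trees:
        raise TreeValidationError("consensus of an empty tree list")
    if not 0.5 <= threshold < 1:
        raise ValueError("threshold must lie in [0.5, 1)")
    universe = trees[0].taxa
    for t in trees[1:]:
        _check_same_taxa(trees[0], t)

    counts: Counter[Bipartition] = Counter()
    for t in trees:
        counts.update(bipartitions(t))
    n = len(trees)
    retained = [(bip, c / n) for bip, c in counts.items() if c / n > threshold]
    # larger clades first so each split nests under already-placed ones
    retained.sort(key=lambda item: -len(item[0].member_set))

    root = TreeNode()
    leaf_nodes = {name: root.add_child(TreeNode(name)) for name in sorted(universe)}
    below: dict[TreeNode, frozenset[str]] = {v: frozenset([k]) for k, v in leaf_nodes.items()}

    for bip, freq in retained:
        members = bip.member_set
        node = root
        while True:
            host = None
            for child in node.children:
                if not child.is_leaf and members < below[child]:
                    host = child
                    break
            if host is None:
                break
            node = host
        grouped = [c for c in node.children if below[c] <= members]
        new = TreeNode(support=freq)
        for c in grouped:
            node.children.remove(c)
            new.add_child(c)
        node.add_child(new)
        below[new] = frozenset(members)
    return Tree(root)


def collapse_by_support(tree: Tree, threshold: float) -> Tree:
    """Contract every internal edge whose support is strictly below
    ``threshold`` (children re-attach to the grandparent).

    Every internal node that induces a non-trivial split must carry a
    support value.  Resolution never increases.
    """
    out = tree.copy()
    universe = out.taxa
    # a degree-2 root subdivides one unrooted edge: its two child edges carry
    # the same split, so a support label on one side covers the other
    if len(out.root.children) == 2:
        a, b = out.root.children
        if not a.is_leaf and not b.is_leaf:
            if a.support is None:
                a.support = b.support
            elif b.support is None:
                b.support = a.support
    sets = _leafsets(out)
    to_collapse: list[TreeNode] = []
    for node in out.preorder():
        if node is out.root or node.is_leaf:
            continue
        nontrivial = 2 <= len(sets[node]) <= len(universe) - 2
        if node.support is None:
            if nontrivial:
                raise TreeValidationError(
                    "collapse_by_support requires support on every internal node"
                )
            continue
        if node.support < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        parent = node.parent
        idx = parent.children.index(node)
        parent.children[idx:idx + 1] = node.children
        for child in node.children:
            child.parent = parent
    return Tree(out.root)


def annotate_supports(tree: Tree, support_of: dict[Bipartition, float],
                      default: float = 0.0) -> None:
    """Attach support values to the internal nodes of ``tree`` in place,
    looked up by the bipartition each node induces."""
    universe = tree.taxa
    sets = _leafsets(tree)
    for node in tree.preorder():
        if node.is_leaf or node is tree.root:
            continue
        if 2 <= len(sets[node]) <= len(universe) - 2:
            bip = Bipartition.from_leafset(sets[node], universe)
            node.support = support_of.get(bip, default)


def resolution(tree: Tree) -> int:
    """Number of internal vertices of the unrooted topology.

    A fully resolved n-taxon tree scores n - 2; a star tree scores 1.  A
    rooted representation whose root has exactly two children loses that
    root on unrooting, hence the adjustment.
    """
    internal = sum(1 for n in tree.preorder() if not n.is_leaf)
    if len(tree.root.children) == 2:
        internal -= 1
    return internal
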