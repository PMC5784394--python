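"""Mutable array-based representation of an unrooted binary tree.

Engines (parsimony search, ML optimisation, MCMC) operate on this
compact structure and convert to/from :class:`mkphylo.tree.Tree` at
their boundaries.  The tree is stored rooted at one leaf (``root``),
whose single child subtends everything else, so every other node has
exactly one parent edge and internal nodes have exactly two children;
an unrooted binary tree on n leaves then has 2n-3 edges and n-3
internal edges.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .tree import Tree, TreeNode

DEFAULT_BLEN = 0.1


class UTree:
    __slots__ = ("n", "parent", "children", "blen", "root", "_free", "present")

    def __init__(self, n_leaves: int):
        total = 2 * n_leaves - 2
        self.n = n_leaves
        self.parent = [-1] * total
        self.children: list[list[int]] = [[] for _ in range(total)]
        self.blen = [DEFAULT_BLEN] * total
        self.root = -1
        self._free = list(range(total - 1, n_leaves - 1, -1))
        self.present = [False] * total

    # -- construction -------------------------------------------------
    def start(self, a: int, b: int, blen: float = DEFAULT_BLEN) -> None:
        self.root = a
        self.children[a] = [b]
        self.parent[b] = a
        self.blen[b] = blen
        self.present[a] = self.present[b] = True

    def insert_leaf(self, leaf: int, at: int, blen_leaf: float = DEFAULT_BLEN) -> int:
        """Attach ``leaf`` onto the edge above node ``at``; returns the new
        internal node."""
        m = self._free.pop()
        p = self.parent[at]
        self.children[p][self.children[p].index(at)] = m
        self.parent[m] = p
        self.children[m] = [at, leaf]
        self.parent[at] = m
        self.parent[leaf] = m
        half = self.blen[at] / 2.0
        self.blen[m] = half
        self.blen[at] = half
        self.blen[leaf] = blen_leaf
        self.present[m] = self.present[leaf] = True
        return m

    def remove_leaf(self, leaf: int) -> None:
        m = self.parent[leaf]
        (s,) = [c for c in self.children[m] if c != leaf]
        g = self.parent[m]
        self.children[g][self.children[g].index(m)] = s
        self.parent[s] = g
        self.blen[s] += self.blen[m]
        self.children[m] = []
        self.present[m] = self.present[leaf] = False
        self._free.append(m)

    # -- traversal ----------------------------------------------------
    def leaves_present(self) -> list[int]:
        return [i for i in range(self.n) if self.present[i]]

    def nodes(self) -> list[int]:
        return [i for i in range(len(self.parent)) if self.present[i]]

    def topo_order(self) -> list[int]:
        """Internal nodes (excluding the root leaf) children-first."""
        order: list[int] = []
        stack = list(self.children[self.root])
        while stack:
            v = stack.pop()
            if self.children[v]:
                order.append(v)
                stack.extend(self.children[v])
        order.reverse()
        return order

    def edges(self) -> list[int]:
        """Each edge keyed by its child node (every present node but root)."""
        return [v for v in self.nodes() if v != self.root]

    def internal_edges(self) -> list[int]:
        return [v for v in self.nodes()
                if self.children[v] and v != self.root and self.parent[v] != self.root]

    def subtree_nodes(self, v: int) -> list[int]:
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return out

    # -- moves --------------------------------------------------------
    def nni(self, v: int, which: int) -> None:
        """Nearest-neighbour interchange across the internal edge above
        ``v``: swap v's sibling with v's child ``which`` (0 or 1)."""
        p = self.parent[v]
        (s,) = [c for c in self.children[p] if c != v]
        x = self.children[v][which]
        self.children[p][self.children[p].index(s)] = x
        self.children[v][which] = s
        self.parent[s] = v
        self.parent[x] = p

    def spr_targets(self, v: int) -> list[int]:
        """Valid regraft edges after pruning the subtree at ``v``: every
        edge of the reduced tree except the one the subtree came from."""
        sub = set(self.subtree_nodes(v))
        p = self.parent[v]
        (s,) = [c for c in self.children[p] if c != v]
        return [u for u in self.edges() if u not in sub and u != p and u != s]

    def spr(self, v: int, target: int, split_frac: float = 0.5) -> tuple[float, float]:
        """Prune the subtree at ``v`` and regraft onto the edge above
        ``target``.  The two edges flanking the detachment point merge
        (lengths summed); the target edge splits at ``split_frac``.
        Returns (merged_length, target_length_before_split), the
        quantities an MCMC acceptance ratio needs."""
        p = self.parent[v]
        (s,) = [c for c in self.children[p] if c != v]
        g = self.parent[p]
        self.children[g][self.children[g].index(p)] = s
        self.parent[s] = g
        merged = self.blen[s] + self.blen[p]
        self.blen[s] = merged
        # reuse node p as the new attachment point
        L = self.blen[target]
        q = self.parent[target]
        self.children[q][self.children[q].index(target)] = p
        self.parent[p] = q
        self.children[p] = [target, v]
        self.parent[target] = p
        self.parent[v] = p
        self.blen[p] = (1.0 - split_frac) * L
        self.blen[target] = split_frac * L
        return merged, L

    # -- identity / conversion ----------------------------------------
    def split_key(self) -> frozenset[frozenset[int]]:
        """Canonical unrooted-topology identifier: the set of leaf sets
        below each internal edge (root leaf always on the other side)."""
        below: dict[int, frozenset[int]] = {}
        for v in self.topo_order():
            acc: set[int] = set()
            for c in self.children[v]:
                acc |= below.get(c, frozenset([c]))
            below[v] = frozenset(acc)
        return frozenset(below[v] for v in self.internal_edges())

    def assign(self, other: "UTree") -> None:
        """In-place restore from a snapshot (object identity preserved)."""
        self.parent[:] = other.parent
        self.children[:] = [list(c) for c in other.children]
        self.blen[:] = other.blen
        self.root = other.root
        self._free[:] = other._free
        self.present[:] = other.present

    def copy(self) -> "UTree":
        new = UTree(self.n)
        new.parent = list(self.parent)
        new.children = [list(c) for c in self.children]
        new.blen = list(self.blen)
        new.root = self.root
        new._free = list(self._free)
        new.present = list(self.present)
        return new

    def to_tree(self, taxa: Sequence[str], with_lengths: bool = True) -> Tree:
        def build(v: int) -> TreeNode:
            node = TreeNode(
                name=taxa[v] if not self.children[v] else None,
                length=self.blen[v] if with_lengths else None,
            )
            for c in self.children[v]:
                node.add_child(build(c))
            return node

        (c0,) = self.children[self.root]
        root = TreeNode()
        root.add_child(TreeNode(name=taxa[self.root],
                                length=0.0 if with_lengths else None))
        root.add_child(build(c0))
        return Tree(root)

    @classmethod
    def from_tree(cls, tree: Tree, taxa: Sequence[str]) -> "UTree":
        """Orient a (binary, possibly rooted) tree as a UTree over the
        given taxon ordering; a degree-2 root is suppressed."""
        index = {name: i for i, name in enumerate(taxa)}
        adj: dict[int, list[tuple[int, float]]] = {}
        ids: dict[TreeNode, int] = {}
        next_internal = [len(taxa)]

        def nid(node: TreeNode) -> int:
            if node not in ids:
                if node.is_leaf:
                    ids[node] = index[node.name]
                else:
                    ids[node] = next_internal[0]
                    next_internal[0] += 1
            return ids[node]

        def add_edge(a: int, b: int, length: Optional[float]) -> None:
            w = DEFAULT_BLEN if length is None else length
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))

        root = tree.root
        if len(root.children) == 2:
            a, b = root.children
            la = a.length if a.length is not None else None
            lb = b.length if b.length is not None else None
            merged = (0.0 if la is None else la) + (0.0 if lb is None else lb)
            add_edge(nid(a), nid(b), merged if (la is not None or lb is not None) else None)
            starts = [a, b]
        else:
            starts = [root]
        for top in starts:
            stack = [top]
            while stack:
                node = stack.pop()
                for child in node.children:
                    add_edge(nid(node), nid(child), child.length)
                    stack.append(child)

        n = len(taxa)
        ut = cls(n)
        ut.root = 0
        ut.present[0] = True
        ut._free = []
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v in seen:
                    continue
                seen.add(v)
                ut.parent[v] = u
                ut.children[u].append(v)
                ut.blen[v] = w
                ut.present[v] = True
                stack.append(v)
        for v in ut.nodes():
            if ut.children[v] and v != ut.root and len(ut.children[v]) != 2:
                raise ValueError("UTree requires a binary (fully resolved) tree")
        return ut


def random_topology(n: int, rng: np.random.Generator,
                    blen: float = DEFAULT_BLEN) -> UTree:
    """Uniform random-addition topology on leaves 0..n-1."""
    order = list(rng.permutation(n))
    ut = UTree(n)
    ut.start(order[0], order[1], blen)
    for leaf in order[2:]:
        edges = ut.edges()
        at = edges[rng.integers(len(edges))]
        ut.insert_leaf(leaf, at, blen)
    return ut


def nj_topology(dist: np.ndarray, min_blen: float = 1e-8) -> UTree:
    """Neighbour-joining tree from a distance matrix, as a UTree.

    Used as a cheap, reasonable starting topology for likelihood-based
    searches; negative NJ branch estimates are clipped to ``min_blen``.
    """
    n = dist.shape[0]
    if n < 4:
        ut = UTree(n)
        ut.start(0, 1, max(dist[0, 1], min_blen))
        if n == 3:
            ut.insert_leaf(2, 1, max(dist[0, 2], min_blen))
        return ut
    active = list(range(n))
    D = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n) if i < j}

    def d(i, j):
        return D[(i, j)] if i < j else D[(j, i)]

    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    next_id = n
    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if q < best_q:
                    best_q, best = q, (i, j)
        i, j = best
        u = next_id
        next_id += 1
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        adj[u] = []
        adj[u].append((i, max(li, min_blen)))
        adj[i].append((u, max(li, min_blen)))
        adj[u].append((j, max(lj, min_blen)))
        adj[j].append((u, max(lj, min_blen)))
        for k in active:
            if k in (i, j):
                continue
            D[(min(u, k), max(u, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [u]
    i, j = active
    w = max(d(i, j), min_blen)
    adj[i].append((j, w))
    adj[j].append((i, w))

    total = 2 * n - 2
    ut = UTree(n)
    ut.root = 0
    ut.present[0] = True
    ut._free = []
    # NJ internal ids n..2n-3 coincide with UTree's internal id range
    seen = {0}
    stack = [0]
    while stack:
        a = stack.pop()
        for b, w in adj[a]:
            if b in seen:
                continue
            seen.add(b)
            ut.parent[b] = a
            ut.children[a].append(b)
            ut.blen[b] = max(w, min_blen)
            ut.present[b] = True
            stack.append(b)
    return ut
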