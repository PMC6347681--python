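"""Rooted genealogies with branch lengths and per-branch mutations.

The :class:`Genealogy` container is shared by the coalescent simulators, the
phylogeny builder, the subclone-sweep scanner and the fitness machinery.  It
is deliberately array-based: nodes are integer ids, leaves occupy ids
``0 .. n_leaves-1``, and every structural query (children, leaf counts below a
node, traversal orders) is derived from the parent array.  Trees may be
multifurcating (multiple-merger coalescents produce nodes with more than two
children).

Branch ``i`` is the edge above node ``i``; the root's branch length is 0 and
carries no mutations.  Mutations are integer site ids attached to branches;
a site attached to branch ``i`` is carried by every leaf below ``i``.
"""

from __future__ import annotations

import io
from typing import Sequence

import numpy as np


class Genealogy:
    """A rooted tree over integer node ids with branch lengths.

    Parameters
    ----------
    parent
        ``parent[i]`` is the node id of the parent of node ``i``; the root has
        parent ``-1``.  Leaves must be the ids ``0 .. n_leaves-1``.
    blen
        Branch length above each node (the root entry is ignored).
    n_leaves
        Number of leaves.
    leaf_labels
        Optional labels, one per leaf (default ``"seq0", "seq1", ...``).
    """

    def __init__(
        self,
        parent: Sequence[int],
        blen: Sequence[float],
        n_leaves: int,
        leaf_labels: Sequence[str] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64).copy()
        self.n_leaves = int(n_leaves)
        if self.parent.shape != self.blen.shape:
            raise ValueError("parent and blen must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.blen[self.root] = 0.0
        if leaf_labels is None:
            leaf_labels = [f"seq{i}" for i in range(self.n_leaves)]
        if len(leaf_labels) != self.n_leaves:
            raise ValueError("one label per leaf required")
        self.leaf_labels = list(leaf_labels)
        # per-branch mutation site ids
        self.branch_sites: dict[int, list[int]] = {}
        self._children: list[list[int]] | None = None
        self._postorder: np.ndarray | None = None
        self._nleaves_below: np.ndarray | None = None

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def is_leaf(self, v: int) -> bool:
        return v < self.n_leaves

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for v, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(v)
            self._children = ch
        return self._children

    def postorder(self) -> np.ndarray:
        """Node ids in postorder (children before parents)."""
        if self._postorder is None:
            order = np.empty(self.n_nodes, dtype=np.int64)
            idx = 0
            stack = [self.root]
            seen = np.empty(self.n_nodes, dtype=np.int64)
            si = 0
            while stack:
                v = stack.pop()
                seen[si] = v
                si += 1
                stack.extend(self.children[v])
            # reversed DFS-preorder of a tree is a valid postorder
            order[:] = seen[::-1]
            self._postorder = order
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def n_leaves_below(self) -> np.ndarray:
        """Number of leaves in the subtree rooted at each node."""
        if self._nleaves_below is None:
            cnt = np.zeros(self.n_nodes, dtype=np.int64)
            cnt[: self.n_leaves] = 1
            for v in self.postorder():
                p = self.parent[v]
                if p >= 0:
                    cnt[p] += cnt[v]
            self._nleaves_below = cnt
        return self._nleaves_below

    def leaves_below(self, v: int) -> np.ndarray:
        """Leaf ids in the subtree rooted at ``v``."""
        out = []
        stack = [int(v)]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(u)
            else:
                stack.extend(self.children[u])
        return np.array(sorted(out), dtype=np.int64)

    def subtree_nodes(self, v: int) -> list[int]:
        out = []
        stack = [int(v)]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return out

    def total_branch_length(self) -> float:
        return float(self.blen.sum() - self.blen[self.root])

    def depths(self) -> np.ndarray:
        """Distance from the root to each node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.blen[v]
        return d

    # -------------------------------------------------------------- mutations
    def set_branch_sites(self, branch_sites: dict[int, list[int]]) -> None:
        self.branch_sites = {int(k): list(v) for k, v in branch_sites.items()}

    def branch_mutation_counts(self) -> np.ndarray:
        cnt = np.zeros(self.n_nodes, dtype=np.int64)
        for v, sites in self.branch_sites.items():
            cnt[v] = len(sites)
        return cnt

    def total_mutations(self) -> int:
        return int(sum(len(v) for v in self.branch_sites.values()))

    def leaf_site_sets(self) -> list[set[int]]:
        """For each leaf, the set of site ids on its root-to-leaf path."""
        acc: list[set[int] | None] = [None] * self.n_nodes
        acc[self.root] = set(self.branch_sites.get(self.root, ()))
        out: list[set[int]] = [set()] * self.n_leaves
        for v in self.preorder():
            if v == self.root:
                continue
            p = self.parent[v]
            s = set(acc[p])  # type: ignore[arg-type]
            s.update(self.branch_sites.get(v, ()))
            if self.is_leaf(v):
                out[v] = s
            else:
                acc[v] = s
        return out

    # ----------------------------------------------------------------- newick
    def to_newick(self, precision: int = 10) -> str:
        """Serialize as a Newick string with branch lengths."""
        buf = io.StringIO()
        # iterative depth-first serialization
        stack: list[tuple[int, int]] = [(self.root, 0)]  # (node, child index)
        while stack:
            v, ci = stack[-1]
            ch = self.children[v]
            if not ch:  # leaf
                buf.write(_quote_label(self.leaf_labels[v]))
                buf.write(f":{self.blen[v]:.{precision}g}")
                stack.pop()
                continue
            if ci == 0:
                buf.write("(")
            if ci < len(ch):
                if ci > 0:
                    buf.write(",")
                stack[-1] = (v, ci + 1)
                stack.append((ch[ci], 0))
            else:
                buf.write(")")
                if v != self.root:
                    buf.write(f":{self.blen[v]:.{precision}g}")
                stack.pop()
        buf.write(";")
        return buf.getvalue()

    @classmethod
    def from_newick(cls, newick: str) -> "Genealogy":
        """Parse a Newick string (via dendropy) into a Genealogy."""
        import dendropy

        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        dnodes = list(tree.preorder_node_iter())
        leaves = [nd for nd in dnodes if nd.is_leaf()]
        labels = [
            (nd.taxon.label if nd.taxon is not None else (nd.label or f"leaf{i}"))
            for i, nd in enumerate(leaves)
        ]
        ids: dict[int, int] = {}
        for i, nd in enumerate(leaves):
            ids[id(nd)] = i
        nxt = len(leaves)
        for nd in dnodes:
            if not nd.is_leaf():
                ids[id(nd)] = nxt
                nxt += 1
        parent = np.full(nxt, -1, dtype=np.int64)
        blen = np.zeros(nxt)
        for nd in dnodes:
            v = ids[id(nd)]
            if nd.parent_node is not None:
                parent[v] = ids[id(nd.parent_node)]
            if nd.edge.length is not None:
                blen[v] = float(nd.edge.length)
        return cls(parent, blen, len(leaves), labels)

    # ---------------------------------------------------------------- reroot
    def rerooted_above_leaf(self, leaf: int) -> "Genealogy":
        """Return a copy rerooted so that ``leaf``'s parent is the root.

        The tree is treated as unrooted; edges are reoriented away from the
        node to which ``leaf`` attaches.  Idempotent when the leaf's parent is
        already the root.  Branch sites travel with their (undirected) edges.
        """
        if not self.is_leaf(leaf):
            raise ValueError("reroot target must be a leaf")
        old_parent = self.parent
        new_root = int(old_parent[leaf])
        if new_root == self.root:
            out = Genealogy(self.parent, self.blen, self.n_leaves, self.leaf_labels)
            out.set_branch_sites(self.branch_sites)
            return out
        # undirected adjacency with edge attributes keyed by the child node of
        # the original orientation
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = old_parent[v]
            if p >= 0:
                adj[v].append((int(p), v))
                adj[p].append((v, v))
        parent = np.full(self.n_nodes, -1, dtype=np.int64)
        blen = np.zeros(self.n_nodes)
        sites: dict[int, list[int]] = {}
        visited = np.zeros(self.n_nodes, dtype=bool)
        visited[new_root] = True
        stack = [new_root]
        while stack:
            u = stack.pop()
            for w, edge_key in adj[u]:
                if visited[w]:
                    continue
                visited[w] = True
                parent[w] = u
                blen[w] = self.blen[edge_key]
                if edge_key in self.branch_sites:
                    sites[w] = list(self.branch_sites[edge_key])
                stack.append(w)
        out = Genealogy(parent, blen, self.n_leaves, self.leaf_labels)
        out.set_branch_sites(sites)
        return out

    def suppress_unifurcations(self) -> "Genealogy":
        """Collapse internal nodes with a single child (summing branch lengths)."""
        keep = np.ones(self.n_nodes, dtype=bool)
        parent = self.parent.copy()
        blen = self.blen.copy()
        sites = {k: list(v) for k, v in self.branch_sites.items()}
        for v in self.preorder():
            ch = self.children[v]
            if len(ch) == 1 and v != self.root:
                c = ch[0]
                parent[c] = parent[v]
                blen[c] = blen[c] + blen[v]
                merged = sites.pop(v, []) + sites.pop(c, [])
                if merged:
                    sites[c] = merged
                keep[v] = False
        # root with single child: drop root, child becomes root
        # (iterate since chains can occur)
        changed = True
        while changed:
            changed = False
            ch_map: dict[int, list[int]] = {}
            for v in range(self.n_nodes):
                if keep[v] and parent[v] >= 0:
                    ch_map.setdefault(int(parent[v]), []).append(v)
            root = next(v for v in range(self.n_nodes) if keep[v] and parent[v] < 0)
            if len(ch_map.get(root, [])) == 1:
                c = ch_map[root][0]
                parent[c] = -1
                blen[c] = 0.0
                sites.pop(c, None)
                sites.pop(root, None)
                keep[root] = False
                changed = True
        # compact ids, preserving leaf ids first
        old_ids = [v for v in range(self.n_leaves)] + [
            v for v in range(self.n_leaves, self.n_nodes) if keep[v]
        ]
        remap = {old: new for new, old in enumerate(old_ids)}
        n = len(old_ids)
        new_parent = np.full(n, -1, dtype=np.int64)
        new_blen = np.zeros(n)
        new_sites: dict[int, list[int]] = {}
        for old in old_ids:
            v = remap[old]
            p = parent[old]
            new_parent[v] = remap[int(p)] if p >= 0 else -1
            new_blen[v] = blen[old]
            if old in sites:
                new_sites[v] = sites[old]
        out = Genealogy(new_parent, new_blen, self.n_leaves, self.leaf_labels)
        out.set_branch_sites(new_sites)
        return out


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label
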