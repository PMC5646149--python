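"""Rooted genealogies with coalescence times.

Node times are measured in internal coalescent units of ``2 * N_e``
generations, with all leaves at time zero, so that a pair of lineages in a
constant-size population coalesces at rate 1.  Trees are stored as flat
parent/time arrays: leaves occupy indices ``0 .. n_leaves-1``, internal
nodes follow, and the root is the unique node with parent ``-1``.
Multifurcations are allowed (consensus trees and perfect-phylogeny
skeletons use them); simulated and MCMC-sampled trees are binary.
"""

from __future__ import annotations

import numpy as np


class GeneTree:
    """A rooted, possibly multifurcating genealogy.

    Parameters
    ----------
    parent
        Integer array of length ``n_nodes``; ``parent[i]`` is the index of
        node ``i``'s parent, ``-1`` for the root.
    time
        Float array of node times (coalescent units, leaves at 0).  May
        contain NaN for topology-only trees (e.g. perfect-phylogeny
        skeletons before time assignment).
    n_leaves
        Number of leaves; leaves are nodes ``0 .. n_leaves-1``.
    labels
        Leaf labels (haplotype ids).  Defaults to ``hap_0 .. hap_{n-1}``.
    demes
        Optional per-leaf subpopulation assignment (int array).
    """

    __slots__ = ("parent", "time", "n_leaves", "labels", "demes", "_children")

    def __init__(self, parent, time, n_leaves, labels=None, demes=None):
        self.parent = np.asarray(parent, dtype=np.int32)
        self.time = np.asarray(time, dtype=float)
        self.n_leaves = int(n_leaves)
        if labels is None:
            labels = [f"hap_{i}" for i in range(self.n_leaves)]
        if len(labels) != self.n_leaves:
            raise ValueError("labels length must equal n_leaves")
        self.labels = list(labels)
        self.demes = None if demes is None else np.asarray(demes, dtype=np.int32)
        self._children = None

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        return int(roots[0])

    def children(self) -> list[list[int]]:
        """Child lists per node (cached)."""
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def postorder(self) -> list[int]:
        """Node indices, children before parents."""
        ch = self.children()
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in ch[node]:
                    stack.append((c, False))
        return order

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants: single root, >=2 children per
        internal node, strictly increasing times towards the root and
        leaves at time zero (when times are set)."""
        root = self.root
        ch = self.children()
        for i in range(self.n_leaves):
            if ch[i]:
                raise ValueError(f"leaf {i} has children")
        for i in range(self.n_leaves, self.n_nodes):
            if len(ch[i]) < 2:
                raise ValueError(f"internal node {i} has {len(ch[i])} children")
        if not np.any(np.isnan(self.time)):
            if np.any(np.abs(self.time[: self.n_leaves]) > 1e-12):
                raise ValueError("leaves must be at time 0 (ultrametric tree)")
            nonroot = np.arange(self.n_nodes) != root
            bad = self.time[self.parent[nonroot]] <= self.time[nonroot]
            # identical haplotypes may attach at time exactly 0; only flag
            # genuine inversions
            if np.any(self.time[self.parent[nonroot]] < self.time[nonroot]):
                raise ValueError("node times must not decrease towards the root")
            if np.any(bad & (self.time[nonroot] > 0)):
                raise ValueError("internal node times must strictly increase towards the root")

    # ------------------------------------------------------------------
    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        b = np.zeros(self.n_nodes)
        nonroot = self.parent >= 0
        b[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return b

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    @property
    def tmrca(self) -> float:
        """Time to the most recent common ancestor of the whole sample."""
        return float(self.time[self.root])

    def mrca(self, a: int, b: int) -> int:
        """Most recent common ancestor of leaves ``a`` and ``b``."""
        seen = set()
        node = a
        while node >= 0:
            seen.add(node)
            node = int(self.parent[node])
        node = b
        while node not in seen:
            node = int(self.parent[node])
        return node

    def mrca_time(self, a: int, b: int) -> float:
        return float(self.time[self.mrca(a, b)])

    # ------------------------------------------------------------------
    def leaf_masks_packed(self) -> np.ndarray:
        """Per-node leaf sets as bit-packed uint8 rows (np.packbits order)."""
        n_bytes = (self.n_leaves + 7) // 8
        packed = np.zeros((self.n_nodes, n_bytes), dtype=np.uint8)
        eye = np.packbits(np.eye(self.n_leaves, dtype=np.uint8), axis=1)
        packed[: self.n_leaves] = eye
        for node in self.postorder():
            p = self.parent[node]
            if p >= 0:
                np.bitwise_or(packed[p], packed[node], out=packed[p])
        return packed

    def clade_leafset(self, node: int) -> np.ndarray:
        """Boolean leaf membership of the clade below ``node``."""
        packed = self.leaf_masks_packed()
        return np.unpackbits(packed[node])[: self.n_leaves].astype(bool)

    # ------------------------------------------------------------------
    def to_newick(self, label_internal: bool = False) -> str:
        """Newick string with branch lengths in coalescent units."""
        ch = self.children()
        b = self.branch_lengths()
        parts: dict[int, str] = {}
        for node in self.postorder():
            if node < self.n_leaves:
                s = self.labels[node]
            else:
                s = "(" + ",".join(parts.pop(c) for c in ch[node]) + ")"
                if label_internal:
                    s += f"n{node}"
            if self.parent[node] >= 0:
                s += f":{b[node]:.10g}"
            parts[node] = s
        return parts[self.root] + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        """Parse a Newick string (branch lengths in coalescent units)."""
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        leaves = [lf for lf in dtree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
        n = len(leaves)
        # depth from root, then convert to time-above-leaves
        for nd in dtree.preorder_node_iter():
            pl = 0.0 if nd.parent_node is None else nd.parent_node._depth
            nd._depth = pl + (nd.edge.length or 0.0)
        max_depth = max(lf._depth for lf in leaves)
        nodes = list(dtree.preorder_node_iter())
        internal = [nd for nd in nodes if nd.child_nodes()]
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        for j, nd in enumerate(internal):
            index[id(nd)] = n + j
        parent = np.full(n + len(internal), -1, dtype=np.int32)
        time = np.zeros(n + len(internal))
        for nd in nodes:
            i = index[id(nd)]
            time[i] = max_depth - nd._depth
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
        time[:n] = 0.0
        return cls(parent, time, n, labels=labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneTree(n_leaves={self.n_leaves}, n_nodes={self.n_nodes}, tmrca={self.tmrca:.4g})"
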