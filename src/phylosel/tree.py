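"""Unrooted phylogenies, Newick I/O, JC distances and neighbor joining.

A tree is stored as a rooted view (parent/children arrays) of an unrooted
topology: the "root" is just the virtual node from which likelihood
computations are seeded, and by time-reversibility the likelihood does not
depend on its placement (pulley principle).  Branch lengths live on the
child side of each edge, in expected substitutions per site.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

MIN_BRANCH = 1e-8
MAX_BRANCH = 100.0
_DEFAULT_MISSING_BL = 0.05


class Tree:
    """Rooted-view array representation of an unrooted phylogeny.

    Node ids ``0 .. n_tips-1`` are tips, in the order of ``labels``;
    internal nodes follow.  ``parent[root] == -1`` and ``lengths[root]``
    is ignored.
    """

    __slots__ = ("labels", "parent", "children", "lengths", "root", "_flat")

    def __init__(self, labels, parent, children, lengths, root):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [list(c) for c in children]
        self.lengths = np.asarray(lengths, dtype=float)
        self.root = int(root)
        self._flat = None

    def flat_arrays(self):
        """(postorder, child-pointer, child-index) arrays, cached.

        Valid as long as the topology is unchanged; branch-length edits do
        not invalidate it.
        """
        if self._flat is None:
            kptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            for v in range(self.n_nodes):
                kptr[v + 1] = kptr[v] + len(self.children[v])
            kidx = np.empty(max(kptr[-1], 1), dtype=np.int64)
            for v in range(self.n_nodes):
                kidx[kptr[v]:kptr[v + 1]] = self.children[v]
            post = np.array(self.postorder(), dtype=np.int64)
            self._flat = (post, kptr, kidx)
        return self._flat

    # -- basic structure ---------------------------------------------------
    @property
    def n_tips(self):
        return len(self.labels)

    @property
    def n_nodes(self):
        return len(self.parent)

    def edges(self):
        """Node ids carrying a parent edge (all nodes except the root)."""
        return [v for v in range(self.n_nodes) if v != self.root]

    def postorder(self):
        order, stack = [], [self.root]
        seen = [False] * self.n_nodes
        while stack:
            v = stack[-1]
            if not seen[v]:
                seen[v] = True
                stack.extend(self.children[v])
            else:
                stack.pop()
                order.append(v)
        return order

    def preorder(self):
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def copy(self):
        return Tree(self.labels, self.parent.copy(),
                    [list(c) for c in self.children], self.lengths.copy(),
                    self.root)

    def branch_vector(self):
        """Branch lengths indexed by child node id (root slot dropped).

        Stable across copies of the same topology, which makes it a valid
        coordinate system for between-model tree distances.
        """
        keep = np.arange(self.n_nodes) != self.root
        return self.lengths[keep]

    def total_length(self):
        return float(self.branch_vector().sum())

    def topology_key(self):
        """Hashable bipartition set identifying the unrooted topology."""
        tipsets = [frozenset() for _ in range(self.n_nodes)]
        for v in self.postorder():
            if v < self.n_tips:
                tipsets[v] = frozenset([self.labels[v]])
            else:
                s = frozenset()
                for c in self.children[v]:
                    s |= tipsets[c]
                tipsets[v] = s
        alltips = frozenset(self.labels)
        bips = set()
        for v in self.edges():
            side = tipsets[v]
            other = alltips - side
            if len(side) > 1 and len(other) > 1:
                bips.add(frozenset((side, other)))
        return frozenset(bips)

    # -- re-rooting --------------------------------------------------------
    def _adjacency(self):
        adj = {v: [] for v in range(self.n_nodes)}
        for v in self.edges():
            p = self.parent[v]
            adj[v].append((p, self.lengths[v]))
            adj[p].append((v, self.lengths[v]))
        return adj

    def with_root(self, new_root):
        """Return a copy re-oriented so pruning starts from ``new_root``."""
        adj = self._adjacency()
        parent = np.full(self.n_nodes, -1, dtype=np.int64)
        lengths = np.zeros(self.n_nodes)
        children = [[] for _ in range(self.n_nodes)]
        stack = [new_root]
        visited = [False] * self.n_nodes
        visited[new_root] = True
        while stack:
            v = stack.pop()
            for u, bl in adj[v]:
                if not visited[u]:
                    visited[u] = True
                    parent[u] = v
                    lengths[u] = bl
                    children[v].append(u)
                    stack.append(u)
        return Tree(self.labels, parent, children, lengths, new_root)

    @classmethod
    def from_adjacency(cls, adj, labels, root):
        n = len(adj)
        t = cls(labels, np.full(n, -1), [[] for _ in range(n)],
                np.zeros(n), root)
        # reuse with_root machinery by faking arrays from adjacency
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        children = [[] for _ in range(n)]
        visited = [False] * n
        visited[root] = True
        stack = [root]
        while stack:
            v = stack.pop()
            for u, bl in adj[v]:
                if not visited[u]:
                    visited[u] = True
                    parent[u] = v
                    lengths[u] = bl
                    children[v].append(u)
                    stack.append(u)
        t.parent, t.lengths, t.children = parent, lengths, children
        return t

    # -- Newick ------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick, labels=None):
        import dendropy

        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True,
                                   suppress_internal_node_taxa=True)
        except Exception as exc:
            raise FormatError(f"could not parse Newick: {exc}") from None
        # unroot: fuse a bifurcating root edge into its children
        dt.deroot()
        leaves = [lf.taxon.label for lf in dt.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValidationError("duplicate tip labels in Newick tree")
        if labels is None:
            labels = leaves
        else:
            if set(labels) != set(leaves):
                missing = set(labels) ^ set(leaves)
                raise ValidationError(
                    f"tree/alignment taxa mismatch: {sorted(missing)}")
        tip_id = {lab: i for i, lab in enumerate(labels)}
        n_tips = len(labels)
        ids = {}
        next_internal = n_tips
        for nd in dt.postorder_node_iter():
            if nd.is_leaf():
                ids[nd] = tip_id[nd.taxon.label]
            else:
                ids[nd] = next_internal
                next_internal += 1
        n = next_internal
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        children = [[] for _ in range(n)]
        for nd in dt.postorder_node_iter():
            v = ids[nd]
            if nd.parent_node is not None:
                p = ids[nd.parent_node]
                parent[v] = p
                children[p].append(v)
                bl = nd.edge.length
                lengths[v] = _DEFAULT_MISSING_BL if bl is None else float(bl)
        root = ids[dt.seed_node]
        return cls(labels, parent, children, lengths, root)

    def to_newick(self):
        def rec(v):
            if v < self.n_tips and not self.children[v]:
                s = self.labels[v]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v != self.root:
                s += f":{self.lengths[v]:.10g}"
            return s

        return rec(self.root) + ";"


def read_newick(path, labels=None) -> Tree:
    return Tree.from_newick(Path(path).read_text(), labels=labels)


def write_newick(tree: Tree, path=None) -> str:
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Distances and neighbor joining

def jc_distance_matrix(aln, d_max: float = 5.0) -> np.ndarray:
    """Pairwise Jukes-Cantor (DNA) / Poisson-corrected (AA) distances.

    d = -(s-1)/s * ln(1 - s/(s-1) * p) for s states, with p the mismatch
    proportion over shared unambiguously-resolved sites; saturated pairs
    (argument of the log <= 0) are capped at ``d_max``.
    """
    from .msa import ambiguity_map, states_for

    if aln.n_taxa < 3:
        raise ValidationError("need >=3 taxa for a distance matrix")
    states = states_for(aln.datatype)
    amb = ambiguity_map(aln.datatype)
    code = {sym: (states.index(tgt) if len(tgt) == 1 else -1)
            for sym, tgt in amb.items()}
    M = np.vectorize(code.__getitem__)(aln.matrix).astype(np.int64)
    ok = M >= 0
    s = float(len(states))
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            nsh = int(shared.sum())
            if nsh == 0:
                raise ValidationError(
                    f"taxa {aln.taxon_labels[i]!r} and {aln.taxon_labels[j]!r}"
                    " share no unambiguous sites")
            p = float((M[i, shared] != M[j, shared]).mean())
            arg = 1.0 - p * s / (s - 1.0)
            if arg <= 0:
                d = d_max
            else:
                d = -(s - 1.0) / s * np.log(arg)
            D[i, j] = D[j, i] = min(d, d_max)
    return D


def nj_topology(D, labels, min_branch: float = MIN_BRANCH) -> Tree:
    """Neighbor-joining tree; negative branch estimates clamped."""
    D = np.asarray(D, dtype=float)
    if len(labels) < 3:
        raise ValidationError("neighbor joining needs >=3 taxa")
    if D.shape != (len(labels), len(labels)):
        raise ValidationError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValidationError("distance matrix must be nonnegative")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    result = nj(DistanceMatrix(D, ids=[str(x) for x in labels]))
    tree = Tree.from_newick(str(result), labels=list(labels))
    keep = np.arange(tree.n_nodes) != tree.root
    tree.lengths[keep] = np.clip(tree.lengths[keep], min_branch, MAX_BRANCH)
    return tree
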