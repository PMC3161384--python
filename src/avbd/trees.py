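"""Distance-based phylogenetics: NJ, least-squares branch lengths, rooting.

The tree workflow mirrors the classical distance pipeline for gene-family
data: build an unrooted neighbour-joining tree, re-estimate branch lengths
on a fixed topology from a synonymous-substitution (dS) distance matrix by
Fitch–Margoliash weighted least squares, root at the midpoint of the longest
leaf-to-leaf path, and project onto a clock (a "linearized" tree) for
display of relative divergence times. Column bootstrap over the alignment
provides split support.

Trees are :class:`dendropy.Tree` objects throughout; all functions return
new trees and leave their inputs untouched.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import nnls

from .alignment import CodonAlignment


@dataclass
class DistanceMatrix:
    """Symmetric taxon-by-taxon distances; NaN marks undefined (saturated) entries."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate taxon ids")
        if not np.allclose(np.nan_to_num(np.diag(self.values)), 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.values - self.values.T), initial=0.0) > 1e-9:
                raise ValueError("matrix must be symmetric")
            if np.nanmin(self.values, initial=0.0) < -1e-12:
                raise ValueError("distances must be non-negative")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_complete(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return not np.isnan(self.values[off]).any()

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            tokens = fh.read().split()
        n = int(tokens[0])
        ids, rows, k = [], [], 1
        for _ in range(n):
            ids.append(tokens[k])
            row = [float("nan") if v.lower() == "nan" else float(v) for v in tokens[k + 1 : k + 1 + n]]
            rows.append(row)
            k += 1 + n
        return cls(ids=ids, values=np.array(rows))

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, tid in enumerate(self.ids):
                cells = " ".join(
                    "nan" if np.isnan(v) else f"{v:.6f}" for v in self.values[i]
                )
                fh.write(f"{tid}  {cells}\n")


# ---------------------------------------------------------------------------
# neighbour joining


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei agglomeration; returns an unrooted (trifurcating) tree.

    Negative intermediate branch lengths are clamped to zero with the
    deficit moved to the sister branch, preserving the joined pair's total.
    Ties in the Q criterion break deterministically on (row, column) order.
    """
    if d.n < 3:
        raise ValueError("neighbour joining needs at least three taxa")
    if not d.is_complete():
        raise ValueError(
            "distance matrix has undefined entries; impute or exclude those taxa first"
        )
    taxa = dendropy.TaxonNamespace(d.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for tid in d.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(tid))
        nodes.append(node)
    mat = d.values.copy()
    active = list(range(d.n))

    def clamp_pair(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = mat[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = mat[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_row = np.zeros(mat.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = max(0.5 * (mat[i, k] + mat[j, k] - dij), 0.0)
        mat[i, :] = new_row
        mat[:, i] = new_row
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = 0.5 * (mat[a, b] + mat[a, c] - mat[b, c])
    lb = 0.5 * (mat[a, b] + mat[b, c] - mat[a, c])
    lc = 0.5 * (mat[a, c] + mat[b, c] - mat[a, b])
    center = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# least-squares branch lengths (Fitch–Margoliash)


def _leaf_index(tree: dendropy.Tree) -> dict[str, int]:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    return {lab: k for k, lab in enumerate(labels)}


def _edge_incidence(tree: dendropy.Tree, leaf_of: dict[str, int]):
    """List of tree edges and, per edge, the boolean leaf side it separates."""
    n = len(leaf_of)
    edges, sides = [], []
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        mask = np.zeros(n, dtype=bool)
        for lf in node.leaf_iter():
            mask[leaf_of[lf.taxon.label]] = True
        edges.append(node)
        sides.append(mask)
    return edges, sides


def ls_branch_lengths(
    topology: dendropy.Tree, d: DistanceMatrix, power: float = 2.0
) -> dendropy.Tree:
    """Re-estimate branch lengths on a fixed topology from a distance matrix.

    Minimises Σ_{i<j} (d_ij − p_ij)² / d_ij^power over non-negative branch
    lengths, where p_ij is the tree path length — the Fitch–Margoliash
    criterion at the default power 2, ordinary least squares at power 0.
    Undefined (NaN) distances are simply left out of the sum; zero distances
    get unit weight. Solved exactly as a non-negative least-squares problem.
    """
    tree = topology.clone(depth=1)
    if len(tree.seed_node.child_nodes()) == 2 and len(tree.leaf_nodes()) > 2:
        tree.deroot()  # a rooted topology has two non-identifiable root edges
    leaf_of = _leaf_index(tree)
    if sorted(leaf_of) != sorted(d.ids):
        raise ValueError("topology leaves and matrix taxa differ")
    col = {tid: leaf_of[tid] for tid in d.ids}
    edges, sides = _edge_incidence(tree, leaf_of)
    rows, targets, weights = [], [], []
    per_leaf_defined = Counter()
    for i in range(d.n):
        for j in range(i + 1, d.n):
            dij = d.values[i, j]
            if np.isnan(dij):
                continue
            per_leaf_defined[d.ids[i]] += 1
            per_leaf_defined[d.ids[j]] += 1
            a, b = col[d.ids[i]], col[d.ids[j]]
            rows.append([1.0 if side[a] != side[b] else 0.0 for side in sides])
            targets.append(dij)
            weights.append(1.0 if dij == 0 else dij ** (-power))
    missing = [tid for tid in d.ids if per_leaf_defined[tid] == 0]
    if missing:
        raise ValueError(f"all distances undefined for taxa {missing}")
    A = np.asarray(rows)
    y = np.asarray(targets)
    w = np.sqrt(np.asarray(weights))
    lengths, _ = nnls(A * w[:, None], y * w)
    for node, ln in zip(edges, lengths):
        node.edge.length = float(ln)
    return tree


def ls_objective(tree: dendropy.Tree, d: DistanceMatrix, power: float = 2.0) -> float:
    """The weighted least-squares criterion of a tree against a matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    total = 0.0
    for i in range(d.n):
        for j in range(i + 1, d.n):
            dij = d.values[i, j]
            if np.isnan(dij):
                continue
            pij = pdm.distance(taxa[d.ids[i]], taxa[d.ids[j]])
            wt = 1.0 if dij == 0 else dij ** (-power)
            total += wt * (dij - pij) ** 2
    return total


# ---------------------------------------------------------------------------
# midpoint rooting and clock projection


def _adjacency(tree: dendropy.Tree):
    adj: dict = {}
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            ln = float(ch.edge.length or 0.0)
            adj.setdefault(node, []).append((ch, ln))
            adj.setdefault(ch, []).append((node, ln))
    return adj

def _paths_from(start, adj):
    dist = {start: 0.0}
    prev = {start: None}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, ln in adj[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + ln
                prev[nbr] = node
                stack.append(nbr)
    return dist, prev


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties on the diameter break deterministically on the lexicographically
    smallest (label, label) pair. A zero-diameter tree is rooted at the
    first leaf's attachment in label order.
    """
    tree = tree.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least two leaves")
    adj = _adjacency(tree)
    best = None  # (distance, labels, start leaf, end leaf, prev map)
    for lf in leaves:
        dist, prev = _paths_from(lf, adj)
        for other in leaves:
            if other is lf:
                continue
            key = (
                -dist[other],
                tuple(sorted((lf.taxon.label, other.taxon.label))),
            )
            if best is None or key < best[0]:
                best = (key, lf, other, prev, dist)
    (neg_diam, _), start, end, prev, dist = best
    diameter = -neg_diam
    tree.is_rooted = True
    if diameter <= 0:
        target = leaves[0].parent_node or leaves[0]
        tree.reseed_at(target, collapse_unrooted_basal_bifurcation=False)
        return tree
    # walk from end back to start accumulating distance from start
    path = [end]
    while path[-1] is not start:
        path.append(prev[path[-1]])
    path.reverse()  # start ... end
    half = diameter / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        ln = next(l for nbr, l in adj[a] if nbr is b)
        if acc + ln >= half - 1e-12:
            offset = half - acc  # distance from a along edge (a, b)
            if offset <= 1e-12:
                tree.reseed_at(a, collapse_unrooted_basal_bifurcation=False)
            elif ln - offset <= 1e-12:
                tree.reseed_at(b, collapse_unrooted_basal_bifurcation=False)
            else:
                # b is the child of a in current orientation, or vice versa
                if b.parent_node is a:
                    parent, child, from_parent = a, b, offset
                else:
                    parent, child, from_parent = b, a, ln - offset
                parent.remove_child(child)
                mid = dendropy.Node()
                parent.add_child(mid)
                mid.edge.length = from_parent
                mid.add_child(child)
                child.edge.length = ln - from_parent
                tree.reseed_at(mid, collapse_unrooted_basal_bifurcation=False)
            break
        acc += ln
    return tree


def linearize(tree: dendropy.Tree) -> dendropy.Tree:
    """Clock projection: re-assign node heights so all leaves are coeval.

    Each node's height above the leaves becomes the mean of its current
    node-to-leaf path lengths over descendant leaves, lifted where needed to
    keep parents above children; branch lengths are the height differences.
    An already-ultrametric tree is a fixed point.
    """
    tree = tree.clone(depth=1)
    height: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            height[node] = 0.0
            continue
        # mean over descendant leaves of path length node -> leaf
        total, count = 0.0, 0
        for lf in node.leaf_iter():
            d = 0.0
            cur = lf
            while cur is not node:
                d += float(cur.edge.length or 0.0)
                cur = cur.parent_node
            total += d
            count += 1
        h = total / count
        h = max(h, max(height[ch] for ch in node.child_nodes()))
        height[node] = h
    for node in tree.postorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = height[node.parent_node] - height[node]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# bootstrap


def p_distance_matrix(aln: CodonAlignment) -> DistanceMatrix:
    """Proportion of differing codons per pair (simple bootstrap distance)."""
    n = aln.n_seqs
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.pairwise_ungapped(i, j)
            p = float(np.mean(a != b)) if a.size else 0.0
            vals[i, j] = vals[j, i] = p
    return DistanceMatrix(ids=list(aln.ids), values=vals)


def _split_set(tree: dendropy.Tree) -> set[frozenset]:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = labels[0]
    out = set()
    for node in tree.postorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels) - side
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def bootstrap_support(
    aln: CodonAlignment,
    n_reps: int = 100,
    seed: int = 0,
    distance_fn=p_distance_matrix,
) -> dendropy.Tree:
    """Column-bootstrap split support on the full-data NJ tree.

    Resamples codon columns with replacement, rebuilds the NJ tree per
    replicate from ``distance_fn``, and writes the percentage of replicates
    containing each internal split as the node label of the full-data tree.
    """
    if aln.n_seqs < 3:
        raise ValueError("bootstrap needs at least three sequences")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(distance_fn(aln))
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    for _ in range(n_reps):
        rep = aln.resample_sites(rng)
        counts.update(_split_set(neighbor_joining(distance_fn(rep))))
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = labels[0]
    for node in tree.postorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels) - side
        node.label = f"{100.0 * counts[side] / n_reps:.0f}"
    return tree
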