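"""Neighbor-joining phylogeny with bootstrap support, outgroup rooting, and
genotype PCA.

Distances are p-distances on dosages (``|d_i - d_j| / 2`` averaged over sites
called in both accessions).  NJ follows Saitou & Nei with the
Studier-Keppler Q criterion; joins are tie-broken deterministically by the
smallest leaf label contained in each candidate subtree.  Negative branch
lengths are clamped to zero with the deficit transferred to the sister edge,
so additive matrices are recovered exactly and non-additive ones stay
non-negative.

PCA uses the Patterson normalization: center each site by its mean dosage,
scale by ``sqrt(p(1-p))`` with ``p`` the mean allele frequency, mean-impute
missing entries (zero after centering), and eigendecompose the accession
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeDataset


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    n_sites: np.ndarray | None = None  # per-pair count of sites used

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite distances")


class TreeNode:
    """A node; ``length`` is the branch to the parent (None at the root)."""

    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name=None, children=None, length=None, support=None):
        self.name = name
        self.children: list[TreeNode] = children or []
        self.length = length
        self.support = support

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    """Rooted representation; an unrooted tree carries a trifurcating root."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized to the side NOT containing
        the first leaf label (so rooting does not change the set)."""
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        out = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(leaf.name for leaf in node.leaves())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def _newick_node(self, node: TreeNode) -> str:
        if node.is_leaf():
            body = node.name
        else:
            inner = ",".join(self._newick_node(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            body = f"({inner}){label}"
        if node.length is None:
            return body
        return f"{body}:{node.length:.10g}"

    def to_newick(self) -> str:
        return self._newick_node(self.root) + ";"


def pdistance(dataset: GenotypeDataset) -> DistanceMatrix:
    """Pairwise p-distance on dosages over sites non-missing in both."""
    return _pdistance_from_dosages(dataset.dosages, list(dataset.accession_ids))


def _pdistance_from_dosages(dosage_matrix: np.ndarray, labels: list[str]) -> DistanceMatrix:
    n = len(labels)
    if n < 2:
        raise ValueError("need >=2 accessions")
    dos = dosage_matrix.astype(float)
    called = dosage_matrix != MISSING
    dos[~called] = 0.0
    mat = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        shared = called[i] & called
        diff = np.abs(dos[i] - dos) / 2.0
        diff[~shared] = 0.0
        cnt = shared.sum(axis=1)
        if np.any(cnt == 0):
            j = int(np.flatnonzero(cnt == 0)[0])
            if j != i:
                raise ValueError(
                    f"accessions {labels[i]!r} and {labels[j]!r} share no called sites"
                )
        counts[i] = cnt
        with np.errstate(invalid="ignore"):
            mat[i] = diff.sum(axis=1) / np.maximum(cnt, 1)
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(list(labels), mat, counts)


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei NJ with deterministic tie-breaking.

    Returns an unrooted tree (trifurcating root).  Requires >=3 taxa.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("need >=3 taxa")
    if not np.all(np.isfinite(D.matrix)):
        raise ValueError("non-finite distances")
    nodes = [TreeNode(name=lbl) for lbl in D.labels]
    keys = list(D.labels)  # smallest leaf label per active subtree
    d = D.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                if Q[ai, aj] <= qmin + 1e-12:
                    ka, kb = sorted((keys[active[ai]], keys[active[aj]]))
                    if best is None or (ka, kb) < best[0]:
                        best = ((ka, kb), ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2 + (R[ai] - R[aj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = TreeNode(children=[child_i, child_j])
        # grow matrix with the new node
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[new_idx, k] = d[k, new_idx] = dk
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        deficit = -length if length < 0 else 0.0
        nodes[idx].length = max(length, 0.0)
        if deficit:  # spread the deficit over the two sister edges
            for other in (x for x in (a, b, c) if x != idx):
                nodes[other].length = max((nodes[other].length or 0.0) + deficit / 2, 0.0)
    order = sorted((a, b, c), key=lambda k: keys[k])
    root = TreeNode(children=[nodes[k] for k in order])
    return Tree(root)


def bootstrap_support(
    dataset: GenotypeDataset, n_replicates: int = 1000, seed: int = 0
) -> Tree:
    """NJ tree with bootstrap supports on its internal edges.

    Sites are resampled with replacement ``n_replicates`` times; each
    internal bipartition of the full-data tree gets the fraction of
    replicate trees containing it.  ``n_replicates=0`` leaves supports
    absent.
    """
    full = neighbor_joining(pdistance(dataset))
    if n_replicates <= 0:
        return full
    rng = np.random.default_rng(seed)
    target = {bp: 0 for bp in full.bipartitions()}
    for _ in range(n_replicates):
        idx = rng.integers(0, dataset.n_sites, size=dataset.n_sites)
        rep = neighbor_joining(
            _pdistance_from_dosages(dataset.dosages[:, idx], list(dataset.accession_ids))
        )
        for bp in rep.bipartitions():
            if bp in target:
                target[bp] += 1
    all_leaves = frozenset(full.leaf_labels())
    anchor = min(all_leaves)
    for node in full.root.walk():
        if node is full.root or node.is_leaf():
            continue
        side = frozenset(leaf.name for leaf in node.leaves())
        if anchor in side:
            side = all_leaves - side
        if side in target:
            node.support = target[side] / n_replicates
    return full


def _adjacency(tree: Tree):
    """Undirected edge map {id(node): [(neighbor, length)]}; lengths live on
    the child side of each rooted edge."""
    adj: dict[int, list] = {}
    index: dict[int, TreeNode] = {}

    def visit(node: TreeNode):
        index[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            adj.setdefault(id(c), [])
            adj[id(node)].append((c, c.length or 0.0))
            adj[id(c)].append((node, c.length or 0.0))
            visit(c)

    visit(tree.root)
    return adj, index


def root_with_outgroup(tree: Tree, outgroup_label: str) -> Tree:
    """Root at the midpoint of the outgroup's pendant edge."""
    leaves = {leaf.name: leaf for leaf in tree.root.leaves()}
    if outgroup_label not in leaves:
        raise KeyError(f"outgroup {outgroup_label!r} not in tree")
    out_leaf = leaves[outgroup_label]
    adj, _ = _adjacency(tree)
    (attach, pendant_len), = adj[id(out_leaf)]
    half = pendant_len / 2.0

    def rebuild(node: TreeNode, parent: TreeNode | None, length: float | None) -> TreeNode:
        new = TreeNode(name=node.name, length=length, support=node.support)
        for nbr, edge_len in adj[id(node)]:
            if parent is not None and nbr is parent:
                continue
            if nbr is out_leaf:
                continue
            new.children.append(rebuild(nbr, node, edge_len))
        return new

    new_out = TreeNode(name=out_leaf.name, length=half)
    rest = rebuild(attach, out_leaf, half)
    # drop the support of the edge now split by the root; it labels the same
    # bipartition as the root itself
    root = TreeNode(children=[new_out, rest])
    return Tree(root)


def pca_genotypes(
    dataset: GenotypeDataset, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Patterson-normalized genotype PCA.

    Returns ``(scores, eigenvalues)`` where ``scores`` is
    ``(n_accessions, k)``.  Monomorphic sites are dropped; missing entries
    are mean-imputed (zero after centering).  Eigenvector signs are fixed so
    the largest-magnitude loading of each axis is positive.
    """
    if dataset.n_accessions < 2:
        raise ValueError("need >=2 accessions")
    dos = dataset.dosages.astype(float)
    called = dataset.dosages != MISSING
    dos[~called] = np.nan
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(dos, axis=0)
    p = mean / 2.0
    poly = called.any(axis=0) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic")
    X = dos[:, poly] - mean[poly]
    X[np.isnan(X)] = 0.0
    X /= np.sqrt(p[poly] * (1 - p[poly]))
    cov = X @ X.T / X.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    k = n_components or min(10, dataset.n_accessions - 1)
    eigval, eigvec = eigval[:k], eigvec[:, :k]
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    scores = eigvec * np.sqrt(eigval)
    return scores, eigval
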