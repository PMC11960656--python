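"""Tree handling: ensembles, patristic distances, MRCA lookup, simulation.

Trees are dendropy objects throughout; tip labels are normalized Latin
binomials so they join exactly against the trait table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .data import normalize_species_id

__all__ = [
    "PhylogenyEnsemble",
    "DistanceMatrix",
    "load_trees",
    "patristic_distances",
    "node_distance_matrix",
    "mrca_node",
    "tip_heights",
    "is_ultrametric",
    "simulate_yule_tree",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric patristic distance matrix over named tips."""

    labels: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.D < 0):
            raise ValueError("negative patristic distance")

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.D[np.ix_(idx, idx)])


@dataclass
class PhylogenyEnsemble:
    """Ordered collection of rooted trees over one shared tip-label set."""

    trees: list[dendropy.Tree]
    mcc_tree: dendropy.Tree | None = None

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("ensemble must contain at least one tree")
        ref = self.tip_labels
        for i, t in enumerate(self.trees):
            labels = frozenset(l.taxon.label for l in t.leaf_node_iter())
            if labels != ref:
                raise ValueError(f"tree {i} has a different tip-label set")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(
            l.taxon.label for l in self.trees[0].leaf_node_iter()
        )

    def subset(
        self, n_trees: int, rng: np.random.Generator | None = None
    ) -> "PhylogenyEnsemble":
        """First ``n_trees`` trees, or a seeded random subset if rng given."""
        n = min(n_trees, len(self.trees))
        if rng is None:
            picked = self.trees[:n]
        else:
            idx = sorted(rng.choice(len(self.trees), size=n, replace=False))
            picked = [self.trees[i] for i in idx]
        return PhylogenyEnsemble(picked, self.mcc_tree)


def _normalize_tip_labels(tree: dendropy.Tree) -> None:
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = normalize_species_id(leaf.taxon.label)


def load_trees(path, schema: str = "newick") -> PhylogenyEnsemble:
    """Read a Newick (one tree per line) or Nexus tree file as an ensemble."""
    trees = dendropy.TreeList.get(path=str(path), schema=schema)
    out = []
    for t in trees:
        t.is_rooted = True
        _normalize_tip_labels(t)
        out.append(t)
    return PhylogenyEnsemble(out)


def save_trees(ensemble: PhylogenyEnsemble, path) -> None:
    tl = dendropy.TreeList(ensemble.trees)
    tl.write(path=str(path), schema="newick", suppress_rooting=True)


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip patristic distances (sum of branch lengths on the path).

    Computed by accumulating, at every internal node in postorder, the
    root-path lengths of the tip sets of each pair of child subtrees.
    Raises if any non-root edge lacks a branch length.
    """
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has an edge with missing branch length")
        if edge.length < 0:
            raise ValueError("tree has a negative branch length")
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = tuple(l.taxon.label for l in leaves)
    index = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))
    # depth[i] under each node: distance from that node to each descendant tip
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipdist = {index[id(node)]: 0.0}
            continue
        merged: dict[int, float] = {}
        children = node.child_nodes()
        for ci, child in enumerate(children):
            cd = {
                i: d + child.edge.length for i, d in child._tipdist.items()
            }
            for other in children[:ci]:
                od = other._tipdist
                for i, di in cd.items():
                    for j, dj in od.items():
                        dj_full = dj + other.edge.length
                        D[i, j] = D[j, i] = di + dj_full
            merged.update(cd)
        for child in children:
            del child._tipdist
        node._tipdist = merged
    del tree.seed_node._tipdist
    return DistanceMatrix(labels, D)


def node_distance_matrix(tree: dendropy.Tree):
    """Patristic distances between ALL nodes (tips and internal).

    Returns ``(nodes, D)`` where ``nodes`` is the list of nodes in preorder
    and ``D[i, j]`` the path length between them. Used by the threshold-model
    ancestral reconstruction, whose latent liabilities live on every node.
    """
    nodes = list(tree.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    depth = np.zeros(n)
    parent = np.full(n, -1, dtype=int)
    for i, node in enumerate(nodes):
        if node.parent_node is not None:
            p = idx[id(node.parent_node)]
            parent[i] = p
            depth[i] = depth[p] + (node.edge.length or 0.0)
    # distance via LCA: d(u,v) = depth u + depth v - 2 depth(lca)
    D = np.zeros((n, n))
    ancestors = []
    for i in range(n):
        chain = {}
        j = i
        while j != -1:
            chain[j] = None
            j = parent[j]
        ancestors.append(chain)
    for i in range(n):
        for j in range(i + 1, n):
            u = j
            while u not in ancestors[i]:
                u = parent[u]
            D[i, j] = D[j, i] = depth[i] + depth[j] - 2 * depth[u]
    return nodes, D


def mrca_node(tree: dendropy.Tree, taxa) -> dendropy.Node:
    """Shallowest node ancestral to every taxon in ``taxa``."""
    taxa = {normalize_species_id(t) for t in taxa}
    tips = {l.taxon.label: l for l in tree.leaf_node_iter()}
    unknown = sorted(taxa - tips.keys())
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown}")
    nodes = [tips[t] for t in taxa]
    if len(nodes) == 1:
        return nodes[0]
    # intersect root paths
    paths = []
    for nd in nodes:
        path = []
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        paths.append(path[::-1])
    mrca = None
    for level in zip(*paths):
        if all(x is level[0] for x in level):
            mrca = level[0]
        else:
            break
    return mrca


def tip_heights(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip label."""
    heights = {}
    for leaf in tree.leaf_node_iter():
        h, nd = 0.0, leaf
        while nd.parent_node is not None:
            h += nd.edge.length or 0.0
            nd = nd.parent_node
        heights[leaf.taxon.label] = h
    return heights


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    h = np.array(list(tip_heights(tree).values()))
    return bool(np.ptp(h) <= rel_tol * max(h.max(), 1e-300))


def simulate_yule_tree(
    n_tips: int, seed: int, height: float = 1.0, label_prefix: str = "sp"
) -> dendropy.Tree:
    """Pure-birth (Yule) tree rescaled to the given total height.

    Tips are labelled ``sp_0001`` ... in a random order; branching times are
    drawn from the standard Yule process with unit birth rate before
    rescaling, so the rescaled tree is ultrametric with unit height by
    default. Fully reproducible from ``seed``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    from .data import normalize_species_id as _norm

    taxa = dendropy.TaxonNamespace(
        [_norm(f"{label_prefix}_{i + 1:04d}") for i in range(n_tips)]
    )
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # grow: start with a cherry, split a uniformly chosen tip at each event
    tree.seed_node.edge.length = 0.0
    tips = []
    for _ in range(2):
        child = tree.seed_node.new_child(edge_length=0.0)
        tips.append(child)
    while len(tips) < n_tips:
        wait = rng.exponential(1.0 / len(tips))
        for t in tips:
            t.edge.length += wait
        k = rng.integers(len(tips))
        split = tips.pop(k)
        for _ in range(2):
            tips.append(split.new_child(edge_length=0.0))
    final = rng.exponential(1.0 / len(tips))
    for t in tips:
        t.edge.length += final
    order = rng.permutation(n_tips)
    for t, i in zip(tips, order):
        t.taxon = taxa[int(i)]
    # rescale to requested height
    h = max(tip_heights(tree).values())
    scale = height / h
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree
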