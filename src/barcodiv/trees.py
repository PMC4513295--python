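"""Distance-tree construction and tree utilities on dendropy containers.

Neighbor-joining is implemented directly (negative branch estimates are
clamped to zero and ties broken by label order, so runs are deterministic);
UPGMA rides on scipy's average-linkage clustering and yields the ultrametric
fallback chronogram the delimitation step needs when no externally built
chronogram is supplied.
"""

from __future__ import annotations

import numpy as np
import dendropy
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .haplotypes import DistanceMatrix, build_distance_matrix

__all__ = [
    "parse_newick", "write_newick", "is_ultrametric", "node_ages",
    "neighbor_joining", "upgma", "bootstrap_supports", "root_with_outgroup",
    "has_polytomies", "tip_labels",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string; malformed input raises with the parser's position."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def has_polytomies(tree: dendropy.Tree) -> bool:
    return any(len(n.child_nodes()) > 2 for n in tree.preorder_internal_node_iter())


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Distance of each node from the root."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """All root-to-tip path lengths equal within a relative tolerance."""
    depths = node_depths(tree)
    tips = [depths[l] for l in tree.leaf_node_iter()]
    span = max(tips)
    if span == 0:
        return True
    return (max(tips) - min(tips)) <= rel_tol * span


def node_ages(tree: dendropy.Tree, rel_tol: float = 1e-6) -> dict[dendropy.Node, float]:
    """Age (time before present) of every node of an ultrametric tree."""
    if not is_ultrametric(tree, rel_tol):
        raise ValueError("tree is not ultrametric within tolerance")
    depths = node_depths(tree)
    height = max(depths[l] for l in tree.leaf_node_iter())
    ages = {n: max(height - d, 0.0) for n, d in depths.items()}
    for leaf in tree.leaf_node_iter():
        ages[leaf] = 0.0  # tips define the present
    return ages


def _tree_from_children(labels: list[str],
                        merges: list[tuple],
                        rooted: bool) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = rooted
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes[i] = node
    nid = len(labels)
    root = None
    for children in merges:
        parent = dendropy.Node()
        for child_idx, length in children:
            child = nodes[child_idx]
            parent.add_child(child)
            child.edge.length = max(float(length), 0.0)
        nodes[nid] = parent
        root = parent
        nid += 1
    tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical NJ agglomeration (Q-criterion) returning an unrooted tree.

    Ties in Q are broken by the smallest (row, column) index pair under the
    input label order; negative branch-length estimates are clamped to zero.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    D = dm.values.astype(float).copy()
    active = list(range(n))          # indices into `nodes`
    merges: list[tuple] = []
    next_id = n
    idx_of = {i: i for i in range(n)}  # node id -> row in D

    # We maintain D over the active set only, re-indexing after each merge.
    ids = list(range(n))
    while len(ids) > 3:
        m = len(ids)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # first minimum in row-major order = deterministic tie-break
        flat = np.argmin(Q)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        merges.append(((ids[i], li), (ids[j], lj)))
        # distances to the new node
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        ids = [ids[k] for k in keep] + [next_id]
        next_id += 1

    # final trifurcation
    a, b, c = ids
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    merges.append(((a, la), (b, lb), (c, lc)))
    return _tree_from_children(dm.labels, merges, rooted=False)


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Rooted ultrametric tree by average-linkage clustering.

    Node height is half the average distance between the merged clusters, so
    the output always passes the ultrametric check by construction.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("upgma needs at least 2 labels")
    if n == 2:
        h = dm.values[0, 1] / 2.0
        return _tree_from_children(dm.labels, [((0, h), (1, h))], rooted=True)
    Z = linkage(squareform(dm.values, checks=False), method="average")
    heights = {i: 0.0 for i in range(n)}
    merges = []
    for k, (ia, ib, dist, _cnt) in enumerate(Z):
        ia, ib = int(ia), int(ib)
        h = dist / 2.0
        merges.append(((ia, h - heights[ia]), (ib, h - heights[ib])))
        heights[n + k] = h
    return _tree_from_children(dm.labels, merges, rooted=True)


def _bipartition_keys(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions as frozensets of the smaller-side tip labels."""
    all_tips = frozenset(tip_labels(tree))
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(all_tips) - 1:
            continue
        other = all_tips - side
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        out[key] = node
    return out


def bootstrap_supports(alignment: dict[str, str], replicates: int = 100,
                       seed: int = 0, min_overlap: int = 1) -> dendropy.Tree:
    """NJ tree with Felsenstein column-resampling bootstrap supports.

    Support of an internal edge = fraction of replicate NJ trees containing
    the same (unrooted) bipartition; stored in ``node.annotations['support']``
    and as the internal node label.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not alignment:
        raise ValueError("empty alignment")
    labels = sorted(alignment)
    cols = np.array([list(alignment[l]) for l in labels])  # taxa x sites
    n_sites = cols.shape[1]
    ref = neighbor_joining(build_distance_matrix(
        {l: alignment[l] for l in labels}, min_overlap=min_overlap))
    ref_bips = _bipartition_keys(ref)
    hits = {key: 0 for key in ref_bips}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        pick = rng.integers(0, n_sites, size=n_sites)
        boot = {l: "".join(cols[i, pick]) for i, l in enumerate(labels)}
        btree = neighbor_joining(build_distance_matrix(boot, min_overlap=1))
        for key in _bipartition_keys(btree):
            if key in hits:
                hits[key] += 1
    for key, node in ref_bips.items():
        sup = hits[key] / replicates
        node.annotations["support"] = sup
        node.label = f"{sup:.2f}"
    return ref


def root_with_outgroup(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    """Root on the branch separating the outgroup tips from the ingroup."""
    tree = tree.clone(depth=1)
    tips = set(tip_labels(tree))
    out = set(labels)
    if not out or not out.issubset(tips):
        raise ValueError("outgroup labels not found among tips")
    if out == tips:
        raise ValueError("outgroup cannot contain all tips")
    if len(out) == 1:
        leaf = next(l for l in tree.leaf_node_iter()
                    if l.taxon.label in out)
        edge = leaf.edge
    else:
        # root temporarily at an ingroup leaf so outgroup connectivity is testable
        anchor = next(l for l in tree.leaf_node_iter()
                      if l.taxon.label not in out)
        tree.reroot_at_edge(anchor.edge, update_bipartitions=True)
        mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace
                               if t.label in out])
        clade = {l.taxon.label for l in mrca.leaf_iter()}
        if clade != out:
            raise ValueError("outgroup is not monophyletic")
        edge = mrca.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half,
                        update_bipartitions=True)
    tree.is_rooted = True
    return tree
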