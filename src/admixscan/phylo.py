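"""Neighbor-joining trees, locus bootstrap, consensus and outgroup rooting.

Trees are dendropy ``Tree`` objects.  The NJ agglomeration is the
canonical Saitou–Nei algorithm with deterministic tie-breaking (the
candidate pair whose sorted label pair is lexicographically smallest
wins), which makes tree output reproducible across platforms and
invariant to the leaf order of the input matrix.  Negative NJ branch
lengths are clamped to zero and the event recorded on the tree
(``tree.clamped_negative_lengths``).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .popgen import DistanceMatrix, cluster_distance_matrix


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Unrooted NJ tree from a distance matrix (n >= 3 labels)."""
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(D.labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    clamped = 0

    nodes = []
    for lab in D.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        nodes.append(node)
    # per active node: the smallest leaf label beneath (tie-break key)
    keys = list(D.labels)
    dist = np.asarray(D.values, dtype=float).copy()
    active = list(range(n))

    def _set_len(node, value):
        nonlocal clamped
        if value < 0:
            clamped += 1
            value = 0.0
        node.edge.length = float(value)

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    pair = tuple(sorted((keys[active[i]], keys[active[j]])))
                    if best is None or pair < best[0]:
                        best = (pair, i, j)
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        _set_len(nodes[ai], li)
        _set_len(nodes[aj], lj)
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        # distances from the new node to every other active node
        new_d = np.zeros(dist.shape[0] + 1)
        for t, at in enumerate(active):
            if at in (ai, aj):
                continue
            new_d[at] = (dist[ai, at] + dist[aj, at] - dij) / 2.0
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_d[:-1]
        dist[:-1, -1] = new_d[:-1]
        nodes.append(parent)
        keys.append(min(keys[ai], keys[aj]))
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    la = (dist[a, b] + dist[a, c] - dist[b, c]) / 2.0
    lb = (dist[a, b] + dist[b, c] - dist[a, c]) / 2.0
    lc = (dist[a, c] + dist[b, c] - dist[a, b]) / 2.0
    center = tree.seed_node
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        _set_len(node, length)
        center.add_child(node)
    tree.is_rooted = False
    tree.clamped_negative_lengths = clamped
    return tree


def root_with_outgroup(tree: dendropy.Tree, label: str) -> dendropy.Tree:
    """Root at the midpoint of the outgroup's pendant edge."""
    rooted = tree.clone(depth=1)
    leaf = rooted.find_node_with_taxon_label(label)
    if leaf is None:
        raise ValueError(f"outgroup {label!r} not found in tree")
    length = leaf.edge.length if leaf.edge.length is not None else 0.0
    rooted.reroot_at_edge(leaf.edge, length1=length / 2.0, length2=length / 2.0)
    rooted.is_rooted = True
    return rooted


def unroot(tree: dendropy.Tree) -> dendropy.Tree:
    out = tree.clone(depth=1)
    out.deroot()
    out.is_rooted = False
    return out


def _leafset(edge, ref_label: str, tns) -> frozenset:
    """Normalized bipartition: the side not containing the reference leaf."""
    labels = frozenset(t.label for t in edge.bipartition.leafset_taxa(tns))
    all_labels = frozenset(t.label for t in tns)
    if ref_label in labels:
        labels = all_labels - labels
    return labels


def _tree_bipartitions(tree: dendropy.Tree) -> dict:
    """Non-trivial normalized bipartitions -> edge length."""
    tree.encode_bipartitions()
    tns = tree.taxon_namespace
    labels = sorted(t.label for t in tns)
    ref = labels[0]
    n = len(labels)
    out = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        ls = _leafset(edge, ref, tns)
        if 1 < len(ls) < n - 1:
            out[ls] = edge.length
    return out


def majority_consensus(trees) -> dendropy.Tree:
    """Majority-rule consensus; supports (% of trees) on internal nodes.

    Bipartitions present in strictly more than half of the input trees
    are retained; branch lengths are averaged over the trees containing
    each bipartition; conflicting minority bipartitions collapse to
    polytomies.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("no trees given")
    labels = sorted(t.label for t in trees[0].taxon_namespace)
    counts: dict = {}
    lengths: dict = {}
    leaf_lengths: dict = {lab: [] for lab in labels}
    for t in trees:
        got = sorted(tx.label for tx in t.taxon_namespace)
        if got != labels:
            raise ValueError("all trees must share one leaf set")
        for ls, ln in _tree_bipartitions(t).items():
            counts[ls] = counts.get(ls, 0) + 1
            if ln is not None:
                lengths.setdefault(ls, []).append(ln)
        for leaf in t.leaf_node_iter():
            if leaf.edge.length is not None:
                leaf_lengths[leaf.taxon.label].append(leaf.edge.length)

    n_trees = len(trees)
    retained = {
        ls: cnt for ls, cnt in counts.items() if cnt * 2 > n_trees
    }

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    # nest retained bipartitions: parent of a set is its smallest superset
    ordered = sorted(retained, key=len, reverse=True)
    node_of: dict = {}
    for ls in ordered:
        parent = root
        best = None
        for other in ordered:
            if other is not ls and len(other) > len(ls) and ls <= other:
                if best is None or len(other) < len(best):
                    best = other
        if best is not None:
            parent = node_of[best]
        node = dendropy.Node()
        node.label = f"{100.0 * retained[ls] / n_trees:g}"
        node.edge.length = (
            float(np.mean(lengths[ls])) if ls in lengths and lengths[ls] else None
        )
        parent.add_child(node)
        node_of[ls] = node
    for lab in labels:
        parent = root
        best = None
        for ls in ordered:
            if lab in ls and (best is None or len(ls) < len(best)):
                best = ls
        if best is not None:
            parent = node_of[best]
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(lab)
        leaf.edge.length = (
            float(np.mean(leaf_lengths[lab])) if leaf_lengths[lab] else None
        )
        parent.add_child(leaf)
    tree.is_rooted = False
    return tree


def bootstrap_cluster_tree(
    P: np.ndarray,
    labels,
    reps: int = 1000,
    distance: str = "nei_da",
    outgroup: str | None = None,
    seed: int = 0,
) -> dendropy.Tree:
    """Locus-bootstrap NJ tree from cluster allele frequencies.

    SNP columns of ``P`` are resampled with replacement ``reps`` times;
    each replicate's distance matrix (Cavalli-Sforza chord or Nei's DA)
    is run through NJ; the majority-rule consensus carries supports as
    the percentage of replicates containing each bipartition.  If an
    outgroup label is given the consensus is rooted on its pendant edge.
    """
    P = np.asarray(P, float)
    labels = list(labels)
    if P.shape[0] < 3:
        raise ValueError("need at least 3 clusters")
    if P.shape[1] < 2:
        raise ValueError("need at least 2 loci")
    if outgroup is not None and outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among cluster labels")
    rng = np.random.default_rng(seed)
    L = P.shape[1]
    boots = []
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        D = cluster_distance_matrix(P[:, cols], labels, method=distance)
        boots.append(neighbor_joining(D))
    consensus = majority_consensus(boots)
    if outgroup is not None:
        consensus = root_with_outgroup(consensus, outgroup)
    return consensus


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=False,
                unquoted_underscores=True,
            )
        )


def read_newick(path, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", taxon_namespace=taxon_namespace,
        suppress_internal_node_taxa=True,
    )


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted RF distance via normalized bipartition sets."""
    b1 = set(_tree_bipartitions(t1))
    b2 = set(_tree_bipartitions(t2))
    return len(b1 ^ b2)
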