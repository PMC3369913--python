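"""Neighbor-joining tree construction and unrooted-tree queries.

Implements the classical agglomerative NJ algorithm (Q-criterion
selection, limb-length formulas, matrix reduction) with two explicit
conventions so output is deterministic and well-formed:

* ties in the Q minimisation are broken by the lexicographically lowest
  pair of clade labels (a clade's label is its smallest leaf label);
* negative limb lengths are clamped to zero with the deficit transferred
  to the sister limb, preserving the joined pair's path length.

Trees are returned as unrooted :class:`dendropy.Tree` objects (internal
nodes of degree 3; for n = 2 a single edge split evenly across the two
pendant branches), so Newick serialisation, re-parsing and traversal use
a standard toolkit rather than a bespoke tree type.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .distance import DistanceMatrix
from .errors import ValidationError

Tree = dendropy.Tree


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Build an unrooted NJ tree from a distance matrix.

    Raises on undefined (NaN) cells or negative input distances. On an
    additive matrix the generating topology and branch lengths are
    recovered exactly (up to floating-point error).
    """
    if dm.n < 2:
        raise ValidationError("NJ needs >= 2 taxa")
    if np.isnan(dm.values).any():
        raise ValidationError("NJ input contains undefined distances")
    if (dm.values < 0).any():
        raise ValidationError("NJ input contains negative distances")

    tns = dendropy.TaxonNamespace(list(dm.labels))
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    # sort key per active clade: its smallest leaf label
    keys = list(dm.labels)
    d = dm.values.astype(float).copy()
    active = list(range(dm.n))

    def _join(i: int, j: int, li: float, lj: float) -> int:
        """Join active entries i, j under a new internal node; return its
        index in ``nodes``. Negative limbs are clamped, deficit moved to
        the sister limb."""
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        return len(nodes) - 1

    if dm.n == 2:
        half = float(d[0, 1]) / 2.0
        root = _join(0, 1, half, half)
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[root])
        tree.is_rooted = False
        return tree

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    pair_key = tuple(sorted((keys[active[a]],
                                             keys[active[b]])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (totals[a] - totals[b]) / (2 * (m - 2))
        lj = dij - li
        new = _join(i, j, li, lj)
        # reduced distances to the new node
        row = np.zeros(len(nodes))
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new, : new] = row[: new]
        d[: new, new] = row[: new]
        active = [k for k in active if k not in (i, j)] + [new]

    # resolve the final three clades around a central degree-3 node
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = (dij + dik - djk) / 2.0
    lj = (dij + djk - dik) / 2.0
    lk = (dik + djk - dij) / 2.0
    center = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def to_newick(tree: Tree) -> str:
    """Serialise with branch lengths; labels needing quotes are quoted."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,   # labels with spaces are quoted, not mangled
    ).strip()


def from_newick(text: str) -> Tree:
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def leaf_labels(tree: Tree) -> tuple[str, ...]:
    return tuple(lf.taxon.label for lf in tree.leaf_node_iter())


def is_monophyletic(tree: Tree, leaf_subset) -> bool:
    """True iff some edge bipartition isolates exactly ``leaf_subset``.

    Monophyly in the unrooted sense: the full leaf set and singletons are
    trivially monophyletic; unknown leaves raise.
    """
    subset = set(leaf_subset)
    if not subset:
        raise ValidationError("leaf subset must be non-empty")
    all_leaves = set(leaf_labels(tree))
    unknown = subset - all_leaves
    if unknown:
        raise ValidationError(f"unknown leaves: {sorted(unknown)}")
    if subset == all_leaves:
        return True
    complement = all_leaves - subset
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        if clade == subset or clade == complement:
            return True
    return False


def tree_length(tree: Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


def path_distance(tree: Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    return float(pdm.patristic_distance(tns.get_taxon(a),
                                        tns.get_taxon(b)))
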