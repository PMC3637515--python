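"""Neighbor-Joining inference, Newick I/O, and tree comparison.

The NJ implementation is the classical Saitou-Nei agglomeration with the
Q-criterion.  For reproducibility the two places where the algorithm is
under-determined are fixed:

* ties in the Q matrix are resolved toward the lexicographically smallest
  pair of cluster representatives (a cluster is represented by its smallest
  leaf label);
* negative estimated branch lengths are clamped to zero; the difference is
  not redistributed to the sister branch.

Trees are dendropy objects; the output of :func:`nj_tree` is unrooted with
a trifurcating seed node.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .score_matrix import DistanceMatrix


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei Neighbor-Joining on a distance matrix (N >= 3)."""
    n = len(dm)
    if n < 3:
        raise ValueError("Neighbor-Joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(dm.ids))
    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for label in dm.ids:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
        reps.append(label)
    D = dm.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        # Q evaluated on unordered pairs only: the matrix expression
        # (m-2) D - r_i - r_j is asymmetric at the ulp level, which would
        # make the tie rule depend on the triangle searched.
        iu, ju = np.triu_indices(m, k=1)
        q = (m - 2) * D[iu, ju] - r[iu] - r[ju]
        qmin = q.min()
        best = None
        for i, j in zip(iu[q == qmin], ju[q == qmin]):
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        assert best is not None
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        new_row = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep][None, :]])
        last_col = np.append(new_row[keep], 0.0)
        D = np.hstack([D, last_col[:, None]])
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [new_rep]

    center = dendropy.Node()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lengths = [
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        ]
    else:  # pragma: no cover - n >= 3 enforced above
        raise AssertionError
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = max(float(length), 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    """Serialize with unquoted underscores and 10 significant digits."""
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()


def from_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (underscores preserved literally)."""
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return from_newick(fh.read())


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bipartition_set(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions, each encoded as the side not holding the
    lexicographically smallest leaf label."""
    labels = leaf_labels(tree)
    ref = min(labels)
    n = len(labels)
    splits: set[frozenset] = set()
    clade: dict[dendropy.Node, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clade[node] = {node.taxon.label}
        else:
            clade[node] = set().union(*(clade[c] for c in node.child_nodes()))
        if node.parent_node is not None and 2 <= len(clade[node]) <= n - 2:
            side = clade[node]
            if ref in side:
                side = labels - side
            splits.add(frozenset(side))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    non-trivial bipartition sets."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"trees are over different leaf sets "
            f"({sorted(l1 ^ l2)[:5]} ... differ)"
        )
    return len(bipartition_set(t1) ^ bipartition_set(t2))


def reroot_at_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Reroot a copy of the tree at the edge leading to the named leaf."""
    rerooted = tree.clone(depth=1)
    node = rerooted.find_node_with_taxon_label(outgroup_label)
    if node is None:
        raise ValueError(f"no leaf labeled {outgroup_label!r}")
    rerooted.to_outgroup_position(node, update_bipartitions=False)
    rerooted.is_rooted = True
    return rerooted
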