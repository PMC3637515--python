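"""Jackknife resampling of the composite matrix and consensus support.

One jackknife replicate subsamples a fraction of the PSSM columns of the
N x M matrix without replacement, recomputes Euclidean distances on the
surviving columns, and reruns Neighbor-Joining.  Support for a branch is
the percentage of replicate trees containing its bipartition; the
majority-rule consensus keeps exactly the bipartitions present in more
than half the replicates (strict rule; an extended greedy mode is
available).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import dendropy

from .score_matrix import CompositeMatrix, DistanceMatrix, euclidean_distances
from .treebuild import bipartition_set, leaf_labels, nj_tree

DEFAULT_FRACTION = 0.8
DEFAULT_REPLICATES = 5000
DEFAULT_DISPLAY_THRESHOLD = 50.0


@dataclass
class SupportedTree:
    """A tree whose internal branches carry jackknife support percentages.

    ``support`` maps each normalized bipartition (see
    :func:`phyrn.treebuild.bipartition_set`) to a percentage in [0, 100].
    Branches below ``display_threshold`` render as ``-`` (the unsupported
    branch convention).
    """

    tree: dendropy.Tree
    support: dict = field(default_factory=dict)
    n_replicates: int = 0
    display_threshold: float = DEFAULT_DISPLAY_THRESHOLD

    def newick(self) -> str:
        """Newick with support (or ``-``) as internal node labels."""
        labels = leaf_labels(self.tree)
        ref = min(labels)
        n = len(labels)
        annotated = self.tree.clone(depth=1)
        clade: dict = {}
        for node in annotated.postorder_node_iter():
            if node.is_leaf():
                clade[node] = {node.taxon.label}
                continue
            clade[node] = set().union(*(clade[c] for c in node.child_nodes()))
            if node.parent_node is None or not 2 <= len(clade[node]) <= n - 2:
                continue
            side = clade[node]
            if ref in side:
                side = labels - side
            pct = self.support.get(frozenset(side))
            if pct is None:
                continue
            node.label = f"{pct:.1f}" if pct >= self.display_threshold else "-"
        return annotated.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        ).strip()


def subsample_columns(
    n_cols: int, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Sorted indices of ``ceil(fraction * n_cols)`` columns drawn without
    replacement (one jackknife replicate's worth of data points)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * n_cols)
    if k < 2:
        raise ValueError(f"fraction {fraction} keeps {k} of {n_cols} columns; need >= 2")
    return np.sort(rng.choice(n_cols, size=k, replace=False))


def jackknife_replicates(
    matrix: CompositeMatrix,
    fraction: float = DEFAULT_FRACTION,
    n_replicates: int = DEFAULT_REPLICATES,
    rng_seed: int | np.random.Generator = 0,
    masked: str = "zero",
) -> list[dendropy.Tree]:
    """NJ trees from column-subsampled copies of the composite matrix."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    n_cols = len(matrix.pssm_ids)
    if math.ceil(fraction * n_cols) < 2:
        raise ValueError(
            f"fraction {fraction} keeps fewer than 2 of {n_cols} columns"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    trees = []
    for _ in range(n_replicates):
        cols = subsample_columns(n_cols, fraction, rng)
        sub = CompositeMatrix(
            query_ids=list(matrix.query_ids),
            pssm_ids=[matrix.pssm_ids[c] for c in cols],
            values=matrix.values[:, cols],
            retained=matrix.retained[:, cols],
        )
        trees.append(nj_tree(euclidean_distances(sub, masked=masked)))
    return trees


def _count_bipartitions(
    trees: Sequence[dendropy.Tree],
) -> tuple[Counter, set]:
    labels = leaf_labels(trees[0])
    counts: Counter = Counter()
    for tree in trees:
        if leaf_labels(tree) != labels:
            raise ValueError("replicate trees are over different leaf sets")
        counts.update(bipartition_set(tree))
    return counts, labels


def _compatible(a: frozenset, b: frozenset) -> bool:
    # both sides are normalized away from the reference leaf
    return a.isdisjoint(b) or a <= b or b <= a


def _tree_from_clades(
    labels: set, clades: list[frozenset], tns: dendropy.TaxonNamespace
) -> dendropy.Tree:
    """Assemble a (possibly multifurcating) tree from a laminar clade family."""
    root = dendropy.Node()
    ordered = sorted(clades, key=lambda c: (-len(c), sorted(c)))
    node_of: dict[frozenset, dendropy.Node] = {}
    placed: list[frozenset] = []
    for clade in ordered:
        parent = root
        best: frozenset | None = None
        for other in placed:
            if clade < other and (best is None or len(other) < len(best)):
                best = other
        if best is not None:
            parent = node_of[best]
        node = dendropy.Node()
        node.edge.length = None
        parent.add_child(node)
        node_of[clade] = node
        placed.append(clade)
    for label in sorted(labels):
        best = None
        for clade in placed:
            if label in clade and (best is None or len(clade) < len(best)):
                best = clade
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(label)
        (node_of[best] if best is not None else root).add_child(leaf)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def majority_consensus(
    trees: Sequence[dendropy.Tree],
    extended: bool = False,
    display_threshold: float = DEFAULT_DISPLAY_THRESHOLD,
) -> SupportedTree:
    """Majority-rule consensus of replicate trees on a common leaf set.

    Strict rule: the consensus contains exactly the non-trivial
    bipartitions in more than 50% of the input trees.  With
    ``extended=True`` the remaining bipartitions are greedily added in
    order of decreasing frequency when compatible.
    """
    if not trees:
        raise ValueError("need at least one tree")
    counts, labels = _count_bipartitions(trees)
    n = len(trees)
    accepted = [bp for bp, c in counts.items() if c / n > 0.5]
    if extended:
        rest = sorted(
            (bp for bp, c in counts.items() if c / n <= 0.5),
            key=lambda bp: (-counts[bp], sorted(bp)),
        )
        for bp in rest:
            if all(_compatible(bp, acc) for acc in accepted):
                accepted.append(bp)
    tns = dendropy.TaxonNamespace(sorted(labels))
    tree = _tree_from_clades(labels, accepted, tns)
    support = {bp: round(100.0 * counts[bp] / n, 1) for bp in accepted}
    return SupportedTree(
        tree=tree,
        support=support,
        n_replicates=n,
        display_threshold=display_threshold,
    )


def annotate_support(
    reference: dendropy.Tree,
    replicates: Sequence[dendropy.Tree],
    display_threshold: float = DEFAULT_DISPLAY_THRESHOLD,
) -> SupportedTree:
    """Attach replicate bipartition percentages to a reference topology."""
    if not replicates:
        raise ValueError("need at least one replicate")
    counts, labels = _count_bipartitions(replicates)
    if leaf_labels(reference) != labels:
        raise ValueError("reference and replicates are over different leaf sets")
    n = len(replicates)
    support = {
        bp: round(100.0 * counts.get(bp, 0) / n, 1)
        for bp in bipartition_set(reference)
    }
    return SupportedTree(
        tree=reference,
        support=support,
        n_replicates=n,
        display_threshold=display_threshold,
    )
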