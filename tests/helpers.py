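"""Shared test utilities: independent oracles and generators.

Everything here is deliberately implemented independently of the package
internals it is used to check (brute-force enumeration, direct
least-squares fits, explicit path sums), so that agreement is evidence
rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np

import phyrn
from phyrn.seq_formats import DomainRegion, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), n))


def single_sequence_pssm(residues: str, seq_id: str = "seed", n_decoys: int = 40):
    """PSSM built from a lone seed with the seed itself as the database."""
    record = SequenceRecord(id=seq_id, residues=residues)
    region = DomainRegion(
        parent_id=seq_id, start=0, end=len(residues), residues=residues
    )
    return phyrn.build_pssm(
        region, [record], iterations=1, n_decoys=n_decoys, rng_seed=0
    )


def bare_pssm(residues: str, seq_id: str = "seed"):
    """A profile straight from the seed's substitution-matrix rows (no
    database enrichment); usable even for homopolymer seeds."""
    from phyrn.profile import PSSM
    from phyrn.substitution import encode, seed_profile_scores

    return PSSM(
        id=seq_id,
        seed_residues=residues,
        scores=seed_profile_scores(encode(residues)),
    )


def brute_force_local_score(
    query_indices: np.ndarray,
    profile_scores: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal local alignment score by exhaustive enumeration.

    A gapped local alignment is determined by its ordered set of matched
    (query, profile) pairs; residues skipped between consecutive pairs form
    gap runs costing open + (len-1) * extend on each side.  All
    order-preserving pair sets are enumerated (feasible for lengths <= 8).
    """
    nq, L = len(query_indices), profile_scores.shape[0]
    best = 0.0
    for k in range(1, min(nq, L) + 1):
        for qs in itertools.combinations(range(nq), k):
            for ps in itertools.combinations(range(L), k):
                s = 0.0
                for t in range(k):
                    s += profile_scores[ps[t], query_indices[qs[t]]]
                    if t:
                        a = qs[t] - qs[t - 1] - 1
                        b = ps[t] - ps[t - 1] - 1
                        if a:
                            s -= gap_open + (a - 1) * gap_extend
                        if b:
                            s -= gap_open + (b - 1) * gap_extend
                best = max(best, s)
    return best


def patristic_matrix(tree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix by explicit edge-separation sums."""
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    below: dict = {}
    dist = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {node.taxon.label}
        else:
            below[node] = set().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None or not node.edge.length:
            continue
        inside = below[node] & set(labels)
        for a in inside:
            for b in set(labels) - inside:
                i, j = index[a], index[b]
                dist[i, j] += node.edge.length
                dist[j, i] += node.edge.length
    return dist


def random_additive_instance(n_leaves: int, rng: np.random.Generator):
    """A random tree with strictly positive branch lengths and its exact
    additive distance matrix."""
    tree = phyrn.sample_tree(n_leaves, branch_length_mean=1.0, rng=rng)
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    dm = phyrn.DistanceMatrix(ids=labels, values=patristic_matrix(tree, labels))
    return tree, dm


def five_taxon_topologies(labels):
    """All 15 unrooted binary topologies on 5 labels, each as its pair of
    cherries (two disjoint 2-subsets)."""
    out = []
    for pair1 in itertools.combinations(labels, 2):
        rest = [x for x in labels if x not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            top = frozenset({frozenset(pair1), frozenset(pair2)})
            if top not in out:
                out.append(top)
    return out


def minimum_evolution_topology(dm) -> frozenset:
    """Exhaustive minimum-evolution search over all 15 five-taxon
    topologies with OLS branch lengths; returns the winning cherry pair."""
    labels = list(dm.ids)
    assert len(labels) == 5
    pair_index = {
        frozenset(p): k for k, p in enumerate(itertools.combinations(labels, 2))
    }
    d = np.array(
        [dm.values[labels.index(a), labels.index(b)]
         for a, b in itertools.combinations(labels, 2)]
    )
    best = None
    for topology in five_taxon_topologies(labels):
        cherries = [sorted(c) for c in topology]
        # edges: 5 pendant + 2 internal (one per cherry)
        ncol = 7
        A = np.zeros((10, ncol))
        for (a, b), row in zip(itertools.combinations(labels, 2), range(10)):
            A[row, labels.index(a)] = 1
            A[row, labels.index(b)] = 1
            for c, cherry in enumerate(cherries):
                in_cherry = (a in cherry) + (b in cherry)
                if in_cherry == 1:
                    A[row, 5 + c] = 1
        lengths, *_ = np.linalg.lstsq(A, d, rcond=None)
        total = lengths.sum()
        if best is None or total < best[0] - 1e-12:
            best = (total, topology)
    return best[1]


def tree_cherry_pairs(tree) -> frozenset:
    """The 2-leaf sides of the non-trivial bipartitions of a 5-taxon tree."""
    from phyrn.treebuild import bipartition_set, leaf_labels

    labels = leaf_labels(tree)
    out = set()
    for side in bipartition_set(tree):
        small = side if len(side) <= len(labels) - len(side) else labels - side
        out.add(frozenset(small))
    return frozenset(out)
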