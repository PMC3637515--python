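"""End-to-end convenience wrappers over the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy

from . import profile, score_matrix, seq_formats, treebuild
from .profile import PSSMLibrary
from .score_matrix import CompositeMatrix, DistanceMatrix


@dataclass
class PipelineResult:
    library: PSSMLibrary
    matrix: CompositeMatrix
    distances: DistanceMatrix
    tree: dendropy.Tree


def infer_family_tree(
    records: Sequence[seq_formats.SequenceRecord],
    boundaries: Sequence[tuple[str, int, int]],
    evalue_threshold: float = profile.DEFAULT_EVALUE,
    iterations: int = profile.DEFAULT_ITERATIONS,
    pseudocount_weight: float = profile.DEFAULT_PSEUDOCOUNT_WEIGHT,
    n_decoys: int = profile.DEFAULT_N_DECOYS,
    b_fraction: float = score_matrix.DEFAULT_B_FRACTION,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    masked: str = "zero",
    rng_seed: int = 0,
) -> PipelineResult:
    """Domain extraction -> PSSM library -> composite matrix -> NJ tree.

    The full-length records serve both as the PSSM target database and as
    the queries, matching the self-contained family analysis setting.
    """
    seeds = seq_formats.extract_domains(records, boundaries)
    library = profile.build_library(
        seeds,
        records,
        evalue_threshold=evalue_threshold,
        iterations=iterations,
        pseudocount_weight=pseudocount_weight,
        gap_open=gap_open,
        gap_extend=gap_extend,
        n_decoys=n_decoys,
        rng_seed=rng_seed,
    )
    matrix = score_matrix.build_composite_matrix(
        records,
        library,
        gap_open=gap_open,
        gap_extend=gap_extend,
        b_fraction=b_fraction,
    )
    distances = score_matrix.euclidean_distances(matrix, masked=masked)
    tree = treebuild.nj_tree(distances)
    return PipelineResult(
        library=library, matrix=matrix, distances=distances, tree=tree
    )
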