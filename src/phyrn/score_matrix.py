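"""The N x M composite score matrix and derived Euclidean distances.

Every full-length query is aligned against every PSSM in the library; each
cell holds the composite score (percent identity x percent coverage,
0..10000).  Mirroring the per-query report limit of profile search tools,
only the top-scoring fraction ``b_fraction`` of profiles is retained per
query (default 75%); the remaining cells are set to zero and flagged in a
mask.  Pairwise Euclidean distances over the retained matrix rows give the
N x N distance matrix consumed by Neighbor-Joining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .profile import PSSMLibrary
from .profile_align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    ProfileAligner,
    align_query_to_pssm,
)
from .seq_formats import SequenceRecord

DEFAULT_B_FRACTION = 0.75


@dataclass
class CompositeMatrix:
    """N queries x M profiles composite scores with a retention mask."""

    query_ids: list[str]
    pssm_ids: list[str]
    values: np.ndarray  # N x M, retained cells only; masked-out cells are 0
    retained: np.ndarray  # N x M bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        n, m = len(self.query_ids), len(self.pssm_ids)
        if self.values.shape != (n, m) or self.retained.shape != (n, m):
            raise ValueError("matrix dimensions inconsistent with id lists")
        if np.any(self.values[~self.retained] != 0):
            raise ValueError("masked-out cells must be stored as 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        """Write values (and a parallel .mask.tsv with the retention mask)."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("query_id\t" + "\t".join(self.pssm_ids) + "\n")
            for qid, row in zip(self.query_ids, self.values):
                fh.write(qid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        mask_path = path.with_suffix(path.suffix + ".mask.tsv")
        with open(mask_path, "w") as fh:
            fh.write("query_id\t" + "\t".join(self.pssm_ids) + "\n")
            for qid, row in zip(self.query_ids, self.retained):
                fh.write(qid + "\t" + "\t".join("1" if v else "0" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompositeMatrix":
        path = Path(path)
        with open(path) as fh:
            pssm_ids = fh.readline().rstrip("\n").split("\t")[1:]
            query_ids, rows = [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                query_ids.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        values = np.array(rows)
        mask_path = path.with_suffix(path.suffix + ".mask.tsv")
        if mask_path.exists():
            with open(mask_path) as fh:
                fh.readline()
                retained = np.array(
                    [
                        [v == "1" for v in line.rstrip("\n").split("\t")[1:]]
                        for line in fh
                    ]
                )
        else:
            retained = values != 0
        return cls(
            query_ids=query_ids, pssm_ids=pssm_ids, values=values, retained=retained
        )


@dataclass
class DistanceMatrix:
    """Symmetric non-negative N x N distances with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square over ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format (names truncated-free, tab-separated)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.values):
                fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                fields = fh.readline().split()
                ids.append(fields[0])
                rows.append([float(v) for v in fields[1 : n + 1]])
        return cls(ids=ids, values=np.array(rows))


def apply_retention(
    values: np.ndarray, b_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the top ``ceil(b_fraction * M)`` cells per row, zero the rest.

    Ties are broken toward the smaller profile index (stable ordering on
    descending score).
    """
    if not 0 < b_fraction <= 1:
        raise ValueError("b_fraction must be in (0, 1]")
    n, m = values.shape
    keep = math.ceil(b_fraction * m)
    retained = np.zeros((n, m), dtype=bool)
    for i in range(n):
        order = np.argsort(-values[i], kind="stable")
        retained[i, order[:keep]] = True
    out = np.where(retained, values, 0.0)
    return out, retained


def build_composite_matrix(
    queries: Sequence[SequenceRecord],
    library: PSSMLibrary,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    b_fraction: float = DEFAULT_B_FRACTION,
    coverage_ref: str = "pssm",
) -> CompositeMatrix:
    """Score every query against every PSSM and apply the retention rule."""
    if len(queries) < 4:
        raise ValueError("need at least 4 queries to build a useful matrix")
    if len(library) < 2:
        raise ValueError("need at least 2 PSSMs")
    if not 0 < b_fraction <= 1:
        raise ValueError("b_fraction must be in (0, 1]")
    raw = raw_composite_values(queries, library, gap_open, gap_extend, coverage_ref)
    values, retained = apply_retention(raw, b_fraction)
    return CompositeMatrix(
        query_ids=[q.id for q in queries],
        pssm_ids=library.ids,
        values=values,
        retained=retained,
    )


def raw_composite_values(
    queries: Sequence[SequenceRecord],
    library: PSSMLibrary,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    coverage_ref: str = "pssm",
) -> np.ndarray:
    """All-vs-all composite scores with no retention applied."""
    values = np.empty((len(queries), len(library)))
    for m, pssm in enumerate(library):
        aligner = ProfileAligner(pssm.scores, gap_open, gap_extend)
        for i, query in enumerate(queries):
            result = align_query_to_pssm(
                query,
                pssm,
                gap_open,
                gap_extend,
                coverage_ref=coverage_ref,
                aligner=aligner,
            )
            values[i, m] = result.composite
    return values


def euclidean_distances(
    matrix: CompositeMatrix, masked: str = "zero"
) -> DistanceMatrix:
    """Pairwise Euclidean distances between query rows.

    ``masked`` controls how non-retained cells enter the sum: ``"zero"``
    (default) uses the stored zeros; ``"drop"`` restricts each pair to
    columns retained in both rows.
    """
    if masked == "zero":
        condensed = pdist(matrix.values, metric="euclidean")
        values = squareform(condensed)
    elif masked == "drop":
        n = len(matrix.query_ids)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                both = matrix.retained[i] & matrix.retained[j]
                d = math.sqrt(
                    float(
                        np.sum(
                            (matrix.values[i, both] - matrix.values[j, both]) ** 2
                        )
                    )
                )
                values[i, j] = values[j, i] = d
    else:
        raise ValueError("masked must be 'zero' or 'drop'")
    return DistanceMatrix(ids=list(matrix.query_ids), values=values)


def scale_unit(dm: DistanceMatrix) -> DistanceMatrix:
    """Divide all distances by the maximum (display only, never before NJ)."""
    maximum = float(dm.values.max())
    if maximum <= 0:
        raise ValueError("cannot unit-scale an all-zero distance matrix")
    return DistanceMatrix(ids=list(dm.ids), values=dm.values / maximum)
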