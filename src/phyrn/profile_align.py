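"""Local alignment of full-length queries against position-specific profiles.

The optimal local alignment (affine gaps, Gotoh three-state recursion) is
delegated to Biopython's C ``PairwiseAligner``.  A profile of length L is
presented to the aligner as a sequence over L private symbols together with a
square substitution matrix whose (column, residue) block holds the
position-specific scores, so sequence-vs-profile alignment reduces to
sequence-vs-sequence alignment over a larger alphabet.

A gap of length g costs ``gap_open + (g - 1) * gap_extend``.

The alignment statistics are the ones the composite score is built from:

* percent identity — identical (query residue == profile seed residue)
  columns over *all* alignment columns, gap columns included;
* percent coverage — distinct profile positions touched, over the profile
  length L (optionally over the query length);
* composite — the plain product of the two percentages, range 0..10000,
  displayed on a log10 scale 0..4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice
from typing import Optional

import numpy as np
from Bio import Align

from .seq_formats import SequenceRecord
from .substitution import X_SCORE, encode

#: Filler for forbidden symbol pairings in the embedded matrix; local
#: alignments never take them because of the zero floor.
_FORBIDDEN = -1.0e8

#: Co-optimal alignments examined when applying the deterministic tie rule.
_TIE_CAP = 64

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class AlignmentResult:
    """One query-vs-PSSM local alignment and its composite statistics.

    ``aligned_pairs`` lists alignment columns as ``(query_index, profile
    index)`` with ``None`` marking a gap on that side.  ``query_residues``
    keeps the full query string so statistics can be recomputed from the
    result alone.
    """

    query_id: str
    pssm_id: str
    raw_score: float
    query_span: tuple[int, int]
    pssm_span: tuple[int, int]
    aligned_pairs: tuple[tuple[Optional[int], Optional[int]], ...]
    percent_identity: float
    percent_coverage: float
    composite: float
    query_residues: str = field(repr=False, default="")

    @property
    def is_empty(self) -> bool:
        return not self.aligned_pairs


class ProfileAligner:
    """Reusable aligner for one profile score table (L x 20 half-bits)."""

    def __init__(
        self,
        scores: np.ndarray,
        gap_open: float = DEFAULT_GAP_OPEN,
        gap_extend: float = DEFAULT_GAP_EXTEND,
    ):
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20 or scores.shape[0] < 1:
            raise ValueError("profile scores must be an L x 20 array with L >= 1")
        if not np.all(np.isfinite(scores)):
            raise ValueError("profile scores must be finite")
        if not gap_open >= gap_extend > 0:
            raise ValueError("need gap_open >= gap_extend > 0")
        L = scores.shape[0]
        self.length = L
        self.scores = scores
        # residues occupy symbols L..L+20 (20 amino acids + X)
        ext = np.empty((L, 21))
        ext[:, :20] = scores
        ext[:, 20] = X_SCORE
        square = np.full((L + 21, L + 21), _FORBIDDEN)
        square[:L, L:] = ext
        square[L:, :L] = ext.T
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.open_gap_score = -float(gap_open)
        aligner.extend_gap_score = -float(gap_extend)
        aligner.substitution_matrix = square
        self._aligner = aligner
        self._profile_seq = np.arange(L, dtype=np.int32)

    def _encode_query(self, query_indices: np.ndarray) -> np.ndarray:
        return (query_indices + self.length).astype(np.int32)

    def score(self, query_indices: np.ndarray) -> float:
        """Optimal local alignment score (no traceback)."""
        if len(query_indices) == 0:
            raise ValueError("empty query")
        return float(
            self._aligner.score(self._profile_seq, self._encode_query(query_indices))
        )

    def align(
        self, query_indices: np.ndarray
    ) -> tuple[float, tuple[tuple[Optional[int], Optional[int]], ...]]:
        """Optimal local alignment with traceback.

        Among co-optimal alignments (up to a fixed cap) the one with the
        smallest ``(query_start, profile_start)``, then the fewest columns,
        is returned.  A non-positive optimum yields the empty alignment.
        """
        if len(query_indices) == 0:
            raise ValueError("empty query")
        q = self._encode_query(query_indices)
        score = float(self._aligner.score(self._profile_seq, q))
        if score <= 0:
            return 0.0, ()
        best = None
        for aln in islice(self._aligner.align(self._profile_seq, q), _TIE_CAP):
            pairs = _pairs_from_coordinates(aln.coordinates)
            q_start = next(qi for qi, _ in pairs if qi is not None)
            p_start = next(pj for _, pj in pairs if pj is not None)
            key = (q_start, p_start, len(pairs))
            if best is None or key < best[0]:
                best = (key, pairs)
        assert best is not None
        return score, best[1]


def _pairs_from_coordinates(
    coordinates: np.ndarray,
) -> tuple[tuple[Optional[int], Optional[int]], ...]:
    """Expand a Biopython alignment path (rows: target=profile, query)."""
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    t, q = coordinates
    for k in range(coordinates.shape[1] - 1):
        dt, dq = t[k + 1] - t[k], q[k + 1] - q[k]
        if dt and dq:  # diagonal run
            for step in range(dt):
                pairs.append((int(q[k] + step), int(t[k] + step)))
        elif dt:
            for step in range(dt):
                pairs.append((None, int(t[k] + step)))
        else:
            for step in range(dq):
                pairs.append((int(q[k] + step), None))
    return tuple(pairs)


def _stats_from_pairs(
    pairs: tuple[tuple[Optional[int], Optional[int]], ...],
    query_indices: np.ndarray,
    seed_indices: np.ndarray,
    coverage_denominator: int,
) -> tuple[float, float, float]:
    if not pairs:
        return 0.0, 0.0, 0.0
    n_columns = len(pairs)
    matches = 0
    covered: set[int] = set()
    for qi, pj in pairs:
        if pj is not None:
            covered.add(pj)
        if qi is not None and pj is not None:
            a = query_indices[qi]
            if a < 20 and a == seed_indices[pj]:
                matches += 1
    identity = 100.0 * matches / n_columns
    coverage = 100.0 * len(covered) / coverage_denominator
    return identity, coverage, identity * coverage / 100.0 * 100.0


def align_query_to_pssm(
    query: SequenceRecord,
    pssm,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    coverage_ref: str = "pssm",
    aligner: ProfileAligner | None = None,
) -> AlignmentResult:
    """Align a full-length query against one PSSM.

    ``coverage_ref`` selects the coverage denominator: the profile length
    (``"pssm"``, default — the score measures how much of the conserved
    domain is matched) or the query length (``"query"``).
    """
    if coverage_ref not in ("pssm", "query"):
        raise ValueError("coverage_ref must be 'pssm' or 'query'")
    if aligner is None:
        aligner = ProfileAligner(pssm.scores, gap_open, gap_extend)
    q_idx = encode(query.residues)
    score, pairs = aligner.align(q_idx)
    seed_idx = encode(pssm.seed_residues)
    denom = pssm.length if coverage_ref == "pssm" else len(query.residues)
    identity, coverage, composite = _stats_from_pairs(pairs, q_idx, seed_idx, denom)
    if pairs:
        q_positions = [qi for qi, _ in pairs if qi is not None]
        p_positions = [pj for _, pj in pairs if pj is not None]
        q_span = (min(q_positions), max(q_positions) + 1)
        p_span = (min(p_positions), max(p_positions) + 1)
    else:
        q_span = p_span = (0, 0)
    return AlignmentResult(
        query_id=query.id,
        pssm_id=pssm.id,
        raw_score=score,
        query_span=q_span,
        pssm_span=p_span,
        aligned_pairs=pairs,
        percent_identity=identity,
        percent_coverage=coverage,
        composite=composite,
        query_residues=query.residues,
    )


def alignment_stats(
    alignment: AlignmentResult, pssm, coverage_ref: str = "pssm"
) -> tuple[float, float, float]:
    """Recompute (percent_identity, percent_coverage, composite) for a result."""
    q_idx = encode(alignment.query_residues) if alignment.query_residues else np.array([], dtype=np.int32)
    seed_idx = encode(pssm.seed_residues)
    denom = pssm.length if coverage_ref == "pssm" else len(alignment.query_residues)
    return _stats_from_pairs(alignment.aligned_pairs, q_idx, seed_idx, denom)


def log_scale(composite: float) -> float:
    """Map a composite score in [0, 10000] to the display scale [0, 4]."""
    if composite < 0:
        raise ValueError("composite score cannot be negative")
    return float(np.log10(max(composite, 1.0)))
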