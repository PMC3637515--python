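"""Amino-acid alphabet and BLOSUM62-derived scoring tables.

All profile scores in this package are half-bit log-odds against a single
background distribution.  To keep the log-odds identity ``score == 0 when
observed frequencies equal the background`` *exact*, the background is not
taken from an external table: it is recovered from the (rounded) BLOSUM62
half-bit matrix itself.  Writing ``M = 2**(S/2)`` for the odds-ratio matrix,
the implied joint target frequencies are ``q_ab = p_a p_b M_ab`` and
consistency of the marginals requires ``M p = 1``; solving that linear
system and renormalising ``q`` gives a self-consistent triple
(background, joint, conditional) used for pseudocounts and for the
sequence simulator.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical one-letter amino-acid alphabet, alphabetical order.  This is the
#: column order of every PSSM in the package and of the serialized TSVs.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Index used for the ambiguity code X (scored as a constant, never identical).
X_INDEX = 20

#: Constant half-bit score of X against any profile column (BLAST-like mildly
#: negative).
X_SCORE = -1.0

_AA_TO_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_TO_INDEX["X"] = X_INDEX


def encode(residues: str) -> np.ndarray:
    """Encode an amino-acid string as int32 indices into :data:`AMINO_ACIDS`.

    X encodes as :data:`X_INDEX`.  Raises ``ValueError`` naming the position
    of the first illegal character.
    """
    out = np.empty(len(residues), dtype=np.int32)
    for i, ch in enumerate(residues):
        idx = _AA_TO_INDEX.get(ch)
        if idx is None:
            raise ValueError(
                f"illegal residue {ch!r} at position {i} "
                f"(alphabet is {AMINO_ACIDS} plus X)"
            )
        out[i] = idx
    return out


def decode(indices: np.ndarray) -> str:
    alpha = AMINO_ACIDS + "X"
    return "".join(alpha[i] for i in indices)


@lru_cache(maxsize=1)
def blosum62_half_bits() -> np.ndarray:
    """BLOSUM62 as a 20x20 float array in :data:`AMINO_ACIDS` order."""
    mat = substitution_matrices.load("BLOSUM62")
    s = np.array(
        [[mat[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
    )
    return s


@lru_cache(maxsize=1)
def _frequency_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s = blosum62_half_bits()
    odds = 2.0 ** (s / 2.0)
    # Mp = 1 gives marginals consistent with the rounded log-odds entries.
    p = np.linalg.solve(odds, np.ones(20))
    if np.any(p <= 0):  # pragma: no cover - property of BLOSUM62
        raise RuntimeError("derived background has non-positive entries")
    p /= p.sum()
    joint = np.outer(p, p) * odds
    joint /= joint.sum()
    joint = 0.5 * (joint + joint.T)
    background = joint.sum(axis=1)
    conditional = joint / background[np.newaxis, :]  # conditional[a, j] = P(a | j)
    return background, joint, conditional


def background_frequencies() -> np.ndarray:
    """Background amino-acid frequencies (sum to 1, all positive)."""
    return _frequency_tables()[0].copy()


def target_frequencies() -> np.ndarray:
    """Joint substitution target frequencies q_ab (20x20, sums to 1)."""
    return _frequency_tables()[1].copy()


def conditional_frequencies() -> np.ndarray:
    """``conditional[a, j]`` = probability of residue ``a`` given aligned ``j``."""
    return _frequency_tables()[2].copy()


def seed_profile_scores(seed_indices: np.ndarray) -> np.ndarray:
    """L x 20 half-bit score table for a bare seed sequence.

    Column ``j`` is the BLOSUM62 row of the seed residue at ``j``; this is the
    profile used on the first search iteration, before any database sequence
    has been included.  Seed positions holding X score :data:`X_SCORE`
    everywhere.
    """
    s = blosum62_half_bits()
    out = np.empty((len(seed_indices), 20), dtype=float)
    for j, idx in enumerate(seed_indices):
        out[j] = s[idx] if idx != X_INDEX else X_SCORE
    return out
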