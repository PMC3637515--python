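"""Randomization test and the Difference Ratio statistic.

The Difference Ratio quantifies per-coordinate signal-to-noise of the
composite score matrix.  Each full-length query is randomized in its
linear order of amino acids (a uniform permutation, preserving length and
composition), the randomized copy is aligned against the whole PSSM
library, and the procedure is repeated over replicates.  For every
(query, PSSM) coordinate

    DR = (composite_wt - mean(composite_random)) / SD(composite_random)

i.e. a z-score of the observed composite against its own permutation null.
The population (n-divisor) standard deviation is used by default.  Where
the null is degenerate (zero SD, typically because every randomized
composite is 0) the DR is defined as 0 when the wild-type score equals the
null mean and as a signed sentinel (default 1e4) otherwise.

Retention (the top-75% reporting rule) is *not* applied here: both
wild-type and randomized scores are raw composites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .profile import PSSMLibrary
from .profile_align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    ProfileAligner,
    _stats_from_pairs,
)
from .score_matrix import raw_composite_values
from .seq_formats import SequenceRecord
from .substitution import encode

DEFAULT_DR_REPLICATES = 100
DEFAULT_SENTINEL = 1e4


def shuffle_sequence(
    record: SequenceRecord, rng: np.random.Generator
) -> SequenceRecord:
    """Uniformly permute the residues of a sequence (Fisher-Yates)."""
    shuffled = "".join(np.array(list(record.residues))[rng.permutation(len(record))])
    return SequenceRecord(
        id=record.id, residues=shuffled, description=record.description
    )


@dataclass
class DifferenceRatioMatrix:
    """Wild-type composites, permutation-null moments, and DR values."""

    query_ids: list[str]
    pssm_ids: list[str]
    wt: np.ndarray
    rand_mean: np.ndarray
    rand_sd: np.ndarray
    dr: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        shape = (len(self.query_ids), len(self.pssm_ids))
        for name in ("wt", "rand_mean", "rand_sd", "dr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.rand_sd < 0):
            raise ValueError("rand_sd must be non-negative")

    def to_tsv(self, path: str | Path, which: str = "dr") -> None:
        arr = getattr(self, which)
        with open(path, "w") as fh:
            fh.write("query_id\t" + "\t".join(self.pssm_ids) + "\n")
            for qid, row in zip(self.query_ids, arr):
                fh.write(qid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    def heatmap(self, path: str | Path, which: str = "dr") -> None:
        """Log-scaled heat map (wild-type composites or DR values)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if which == "wt":
            data, vmax, label = np.log10(np.maximum(self.wt, 1.0)), 4.0, "log10 composite"
        else:
            data, vmax, label = dr_log_display(self.dr), None, "log10 DR"
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(data, aspect="auto", cmap="jet", vmin=0.0, vmax=vmax)
        ax.set_xlabel("PSSM")
        ax.set_ylabel("query")
        fig.colorbar(im, ax=ax, label=label)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def compute_dr(wt, rand_mean, rand_sd, sentinel: float = DEFAULT_SENTINEL):
    """Elementwise Difference Ratio: (wt - mean) / SD of the permutation null.

    Degenerate coordinates (zero SD) map to 0 when the wild-type score
    equals the null mean and to a signed sentinel otherwise.
    """
    scalar = np.isscalar(wt) and np.isscalar(rand_mean) and np.isscalar(rand_sd)
    wt, rand_mean, rand_sd = (
        np.atleast_1d(np.asarray(x, dtype=float)) for x in (wt, rand_mean, rand_sd)
    )
    wt, rand_mean, rand_sd = np.broadcast_arrays(wt, rand_mean, rand_sd)
    dr = np.zeros(wt.shape)
    positive = rand_sd > 0
    diff = wt - rand_mean
    dr[positive] = diff[positive] / rand_sd[positive]
    tol = 1e-9 * np.maximum(1.0, np.abs(wt))
    capped = ~positive & (np.abs(diff) > tol)
    dr[capped] = np.sign(diff)[capped] * sentinel
    return float(dr[0]) if scalar else dr


def difference_ratio(
    queries: Sequence[SequenceRecord],
    library: PSSMLibrary,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    n_replicates: int = DEFAULT_DR_REPLICATES,
    rng_seed: int | np.random.Generator = 0,
    sd_mode: str = "population",
    sentinel: float = DEFAULT_SENTINEL,
    coverage_ref: str = "pssm",
) -> DifferenceRatioMatrix:
    """Compute the Difference Ratio matrix for queries against a library.

    One fresh shuffle per query per replicate (not per query-PSSM pair);
    each shuffle is aligned against all M PSSMs.  Deterministic given
    ``rng_seed``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 randomization replicates")
    if sd_mode not in ("population", "sample"):
        raise ValueError("sd_mode must be 'population' or 'sample'")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    wt = raw_composite_values(
        queries, library, gap_open, gap_extend, coverage_ref=coverage_ref
    )
    n, m = wt.shape
    aligners = [ProfileAligner(p.scores, gap_open, gap_extend) for p in library]
    seed_idx = [encode(p.seed_residues) for p in library]
    denom = [
        (p.length if coverage_ref == "pssm" else None) for p in library
    ]
    q_idx = [encode(q.residues) for q in queries]
    # Welford streaming moments: exact zero variance when every replicate
    # scores identically (the shuffle-invariant query case)
    mean = np.zeros((n, m))
    m2 = np.zeros((n, m))
    sample = np.empty((n, m))
    for r in range(1, n_replicates + 1):
        for i in range(n):
            shuffled = q_idx[i][rng.permutation(len(q_idx[i]))]
            for j in range(m):
                _, pairs = aligners[j].align(shuffled)
                d = denom[j] if denom[j] is not None else len(shuffled)
                _, _, composite = _stats_from_pairs(
                    pairs, shuffled, seed_idx[j], d
                )
                sample[i, j] = composite
        delta = sample - mean
        mean += delta / r
        m2 += delta * (sample - mean)
    divisor = n_replicates if sd_mode == "population" else n_replicates - 1
    sd = np.sqrt(np.maximum(m2, 0.0) / divisor)
    dr = compute_dr(wt, mean, sd, sentinel=sentinel)
    return DifferenceRatioMatrix(
        query_ids=[q.id for q in queries],
        pssm_ids=library.ids,
        wt=wt,
        rand_mean=mean,
        rand_sd=sd,
        dr=dr,
        n_replicates=n_replicates,
    )


def dr_log_display(dr):
    """log10(max(DR, 1)) for rendering; monotone non-decreasing."""
    return np.log10(np.maximum(np.asarray(dr, dtype=float), 1.0))
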