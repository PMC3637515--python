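"""Position-specific scoring matrix (PSSM) construction and calibration.

Each seed domain region yields one PSSM.  Construction is iterative, in the
style of profile search tools: the seed (scored through BLOSUM62 on the
first pass) is searched against a target database, database sequences whose
alignment is significant at the configured E-value threshold are included,
and column scores are rebuilt from the included alignment.  Subsequent
iterations re-search the database with the updated profile.

Statistical significance is empirical: maximal local-alignment scores of
residue-shuffled decoys are fitted with a Gumbel (extreme value)
distribution by the method of moments, and
``E(s) = n_db * (1 - exp(-exp(-lambda * (s - mu))))``.

Column modelling:

* Henikoff position-based sequence weights over the included rows;
* PSI-BLAST-style pseudocounts, mixing observed weighted frequencies ``f``
  with the substitution-prior expectation ``g_a = sum_j f_j P(a|j)`` at
  weight ``beta`` against the data weight ``alpha`` = (mean number of
  distinct residues per column) - 1;
* half-bit log-odds against the package background.

A column whose observed frequencies equal the background therefore scores
exactly zero at any ``beta``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .profile_align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    ProfileAligner,
)
from .seq_formats import DomainRegion, SequenceRecord
from .substitution import (
    AMINO_ACIDS,
    X_INDEX,
    background_frequencies,
    conditional_frequencies,
    encode,
    seed_profile_scores,
)

DEFAULT_EVALUE = 7e-13
DEFAULT_ITERATIONS = 3
DEFAULT_PSEUDOCOUNT_WEIGHT = 10.0
DEFAULT_N_DECOYS = 200

_EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class ScoreCalibration:
    """Gumbel fit to decoy maximal local-alignment scores."""

    mu: float
    lam: float
    n_decoys: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel scale must be positive")
        if self.n_decoys < 30:
            raise ValueError("need at least 30 decoys for calibration")

    def pvalue(self, score: float) -> float:
        """Upper-tail probability of a single decoy reaching ``score``."""
        x = self.lam * (score - self.mu)
        if x < -30:
            return 1.0
        return float(-np.expm1(-np.exp(-x)))

    def evalue(self, score: float, n_db: int) -> float:
        """Expected number of database hits at or above ``score``."""
        return n_db * self.pvalue(score)


@dataclass
class PSSM:
    """A position-specific score model built from one seed domain region."""

    id: str
    seed_residues: str
    scores: np.ndarray  # L x 20, half-bit log-odds
    n_contributing: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape != (len(self.seed_residues), 20):
            raise ValueError(
                f"PSSM {self.id!r}: scores must be L x 20 with "
                f"L == len(seed_residues)"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM {self.id!r}: empty profile")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"PSSM {self.id!r}: non-finite scores")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class PSSMLibrary:
    """An ordered collection of PSSMs sharing one background model."""

    pssms: list[PSSM]
    background: np.ndarray = field(default_factory=background_frequencies)
    build_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pssms]
        if len(set(ids)) != len(ids):
            raise ValueError("PSSM ids must be unique within a library")
        self.background = np.asarray(self.background, dtype=float)
        if np.any(self.background <= 0) or abs(self.background.sum() - 1.0) > 1e-12:
            raise ValueError("background must be positive and sum to 1")

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pssms]

    def __len__(self) -> int:
        return len(self.pssms)

    def __iter__(self):
        return iter(self.pssms)

    def __getitem__(self, i: int) -> PSSM:
        return self.pssms[i]

    def save(self, directory: str | Path) -> None:
        """Serialize as per-profile TSV matrices plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for i, pssm in enumerate(self.pssms):
            fname = f"pssm_{i:04d}.tsv"
            with open(directory / fname, "w") as fh:
                fh.write("\t".join(AMINO_ACIDS) + "\n")
                for row in pssm.scores:
                    fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")
            entries.append(
                {
                    "id": pssm.id,
                    "file": fname,
                    "length": pssm.length,
                    "seed_residues": pssm.seed_residues,
                    "n_contributing": pssm.n_contributing,
                }
            )
        manifest = {
            "pssms": entries,
            "background": self.background.tolist(),
            "build_params": self.build_params,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "PSSMLibrary":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        pssms = []
        for entry in manifest["pssms"]:
            with open(directory / entry["file"]) as fh:
                header = fh.readline().strip().split("\t")
                if "".join(header) != AMINO_ACIDS:
                    raise ValueError(
                        f"{entry['file']}: header must be amino-acid order "
                        f"{AMINO_ACIDS}"
                    )
                scores = np.loadtxt(fh, delimiter="\t", ndmin=2)
            pssms.append(
                PSSM(
                    id=entry["id"],
                    seed_residues=entry["seed_residues"],
                    scores=scores,
                    n_contributing=entry.get("n_contributing", 0),
                )
            )
        return cls(
            pssms=pssms,
            background=np.array(manifest["background"]),
            build_params=manifest.get("build_params", {}),
        )


def _decoy_scores(
    aligner: ProfileAligner,
    target_db: Sequence[SequenceRecord],
    n_decoys: int,
    rng: np.random.Generator,
) -> np.ndarray:
    scores = np.empty(n_decoys)
    db_idx = [encode(rec.residues) for rec in target_db]
    for k in range(n_decoys):
        src = db_idx[rng.integers(len(db_idx))]
        scores[k] = aligner.score(rng.permutation(src))
    return scores


def _fit_gumbel(scores: np.ndarray, n_decoys: int) -> ScoreCalibration:
    sd = float(np.std(scores))
    if sd == 0:
        raise ValueError(
            "decoy score distribution is degenerate (zero variance); "
            "increase the number of decoys or the database diversity"
        )
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(np.mean(scores)) - _EULER_GAMMA / lam
    return ScoreCalibration(mu=mu, lam=lam, n_decoys=n_decoys)


def calibrate_scores(
    profile_scores: np.ndarray,
    target_db: Sequence[SequenceRecord],
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int | np.random.Generator = 0,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ScoreCalibration:
    """Fit the decoy score distribution for one profile.

    Decoys are residue-shuffled copies of database sequences drawn with
    replacement, so they preserve length and composition but no positional
    signal.
    """
    if n_decoys < 30:
        raise ValueError("need at least 30 decoys for calibration")
    if not target_db:
        raise ValueError("target database is empty")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    aligner = ProfileAligner(profile_scores, gap_open, gap_extend)
    return _fit_gumbel(_decoy_scores(aligner, target_db, n_decoys, rng), n_decoys)


def _henikoff_weights(rows: np.ndarray) -> np.ndarray:
    """Position-based sequence weights; ``rows`` is n x L with -1 for gaps."""
    n, L = rows.shape
    weights = np.zeros(n)
    for j in range(L):
        col = rows[:, j]
        present = col >= 0
        if not present.any():
            continue
        values, counts = np.unique(col[present], return_counts=True)
        r = len(values)
        count_of = dict(zip(values.tolist(), counts.tolist()))
        for k in np.nonzero(present)[0]:
            weights[k] += 1.0 / (r * count_of[col[k]])
    total = weights.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return weights / total


def _scores_from_rows(rows: np.ndarray, pseudocount_weight: float) -> np.ndarray:
    """Half-bit log-odds columns from an n x L gapped residue-index matrix."""
    background = background_frequencies()
    conditional = conditional_frequencies()
    n, L = rows.shape
    weights = _henikoff_weights(rows)
    freqs = np.empty((L, 20))
    distinct = np.empty(L)
    for j in range(L):
        col = rows[:, j]
        present = col >= 0
        if not present.any():
            freqs[j] = background
            distinct[j] = 1
            continue
        f = np.zeros(20)
        wsum = 0.0
        for k in np.nonzero(present)[0]:
            f[col[k]] += weights[k]
            wsum += weights[k]
        freqs[j] = f / wsum
        distinct[j] = len(np.unique(col[present]))
    alpha = max(float(distinct.mean()) - 1.0, 0.0)
    beta = float(pseudocount_weight)
    scores = np.empty((L, 20))
    for j in range(L):
        g = conditional @ freqs[j]
        if alpha + beta > 0:
            q = (alpha * freqs[j] + beta * g) / (alpha + beta)
        else:
            q = freqs[j]
        q = np.maximum(q, 1e-12)
        scores[j] = 2.0 * np.log2(q / background)
    return scores


def build_pssm(
    seed: DomainRegion,
    target_db: Sequence[SequenceRecord],
    evalue_threshold: float = DEFAULT_EVALUE,
    iterations: int = DEFAULT_ITERATIONS,
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT_WEIGHT,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int | np.random.Generator = 0,
) -> PSSM:
    """Build one PSSM from a seed domain region, enriched against a database.

    The seed always contributes, so every column is defined even when no
    database sequence passes the threshold.  Deterministic given
    ``rng_seed``.
    """
    if not target_db:
        raise ValueError("target database is empty")
    if evalue_threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    if iterations < 1:
        raise ValueError("need at least one search iteration")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    seed_idx = encode(seed.residues)
    L = len(seed_idx)
    scores = seed_profile_scores(seed_idx)
    db_idx = [encode(rec.residues) for rec in target_db]
    n_db = len(target_db)
    n_included = 0
    for _ in range(iterations):
        aligner = ProfileAligner(scores, gap_open, gap_extend)
        calibration = _fit_gumbel(
            _decoy_scores(aligner, target_db, n_decoys, rng), n_decoys
        )
        seed_row = np.where(seed_idx == X_INDEX, -1, seed_idx)
        rows = [seed_row]
        n_included = 0
        for q_idx in db_idx:
            score, pairs = aligner.align(q_idx)
            if not pairs or calibration.evalue(score, n_db) > evalue_threshold:
                continue
            row = np.full(L, -1, dtype=np.int64)
            for qi, pj in pairs:
                if qi is not None and pj is not None and q_idx[qi] != X_INDEX:
                    row[pj] = q_idx[qi]
            rows.append(row)
            n_included += 1
        scores = _scores_from_rows(np.array(rows), pseudocount_weight)
    return PSSM(
        id=seed.parent_id,
        seed_residues=seed.residues,
        scores=scores,
        n_contributing=n_included,
    )


def build_library(
    seeds: Sequence[DomainRegion],
    target_db: Sequence[SequenceRecord],
    evalue_threshold: float = DEFAULT_EVALUE,
    iterations: int = DEFAULT_ITERATIONS,
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT_WEIGHT,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int = 0,
) -> PSSMLibrary:
    """Build the PSSM library: one profile per seed domain region."""
    children = np.random.SeedSequence(rng_seed).spawn(len(seeds))
    pssms = [
        build_pssm(
            seed,
            target_db,
            evalue_threshold=evalue_threshold,
            iterations=iterations,
            pseudocount_weight=pseudocount_weight,
            gap_open=gap_open,
            gap_extend=gap_extend,
            n_decoys=n_decoys,
            rng_seed=np.random.default_rng(child),
        )
        for seed, child in zip(seeds, children)
    ]
    return PSSMLibrary(
        pssms=pssms,
        build_params={
            "evalue_threshold": evalue_threshold,
            "iterations": iterations,
            "pseudocount_weight": pseudocount_weight,
            "gap_open": gap_open,
            "gap_extend": gap_extend,
            "n_decoys": n_decoys,
            "rng_seed": rng_seed,
        },
    )
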