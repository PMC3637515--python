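import numpy as np
import pytest

import phyrn
from helpers import random_protein, single_sequence_pssm
from phyrn.profile import calibrate_scores
from phyrn.seq_formats import DomainRegion, SequenceRecord
from phyrn.substitution import (
    AMINO_ACIDS,
    background_frequencies,
    conditional_frequencies,
    encode,
)


def test_background_is_a_distribution():
    pi = background_frequencies()
    assert pi.shape == (20,)
    assert np.all(pi > 0)
    assert abs(pi.sum() - 1.0) < 1e-12


def test_conditional_marginal_consistency():
    """sum_j pi_j P(a|j) == pi_a, the identity that makes a background-
    frequency column score exactly zero after pseudocount mixing."""
    pi = background_frequencies()
    cond = conditional_frequencies()
    assert np.allclose(cond @ pi, pi, atol=1e-12)


def test_single_sequence_profile_argmax_is_seed(rng):
    seq = random_protein(rng, 50)
    pssm = single_sequence_pssm(seq)
    argmax = pssm.scores.argmax(axis=1)
    assert all(AMINO_ACIDS[a] == r for a, r in zip(argmax, seq))


def test_identical_copies_collapse_to_single_copy(rng):
    """Henikoff weighting makes ten identical database copies equivalent to
    one: the profile is unchanged."""
    seq = random_protein(rng, 40)
    region = DomainRegion(parent_id="s", start=0, end=40, residues=seq)
    one = phyrn.build_pssm(
        region,
        [SequenceRecord(id="s", residues=seq)],
        iterations=1,
        n_decoys=60,
        rng_seed=0,
    )
    many = phyrn.build_pssm(
        region,
        [SequenceRecord(id=f"s{k}", residues=seq) for k in range(10)],
        iterations=1,
        n_decoys=60,
        rng_seed=0,
    )
    assert np.allclose(one.scores, many.scores)


def test_build_pssm_deterministic(small_family):
    seeds = phyrn.extract_domains(
        small_family.leaf_records, small_family.domain_boundaries
    )
    a = phyrn.build_pssm(
        seeds[0], small_family.leaf_records, iterations=1, n_decoys=50, rng_seed=7
    )
    b = phyrn.build_pssm(
        seeds[0], small_family.leaf_records, iterations=1, n_decoys=50, rng_seed=7
    )
    assert np.array_equal(a.scores, b.scores)
    assert a.n_contributing == b.n_contributing


def test_pseudocount_weight_shrinks_toward_prior(small_family):
    """Larger pseudocount weight pulls columns toward the substitution-prior
    expectation (monotone in max-norm)."""
    seeds = phyrn.extract_domains(
        small_family.leaf_records, small_family.domain_boundaries
    )
    kwargs = dict(iterations=1, n_decoys=50, rng_seed=0)
    profiles = {
        beta: phyrn.build_pssm(
            seeds[0], small_family.leaf_records, pseudocount_weight=beta, **kwargs
        )
        for beta in (1.0, 10.0, 100.0, 1e7)
    }
    prior = profiles[1e7].scores  # essentially pure prior
    gaps = [
        np.max(np.abs(profiles[beta].scores - prior)) for beta in (1.0, 10.0, 100.0)
    ]
    assert gaps[0] > gaps[1] > gaps[2]


def test_empty_database_rejected():
    region = DomainRegion(parent_id="s", start=0, end=4, residues="MKVL")
    with pytest.raises(ValueError):
        phyrn.build_pssm(region, [])


def test_degenerate_decoys_rejected():
    """A database of a single repeated residue gives constant decoy scores,
    which cannot calibrate an extreme-value tail."""
    region = DomainRegion(parent_id="s", start=0, end=10, residues="A" * 10)
    db = [SequenceRecord(id="s", residues="A" * 30)]
    with pytest.raises(ValueError, match="degenerate|variance"):
        phyrn.build_pssm(region, db, iterations=1, n_decoys=40)


def test_evalue_monotone_and_db_size_linear(rng):
    db = [
        SequenceRecord(id=f"s{i}", residues=random_protein(rng, 120))
        for i in range(10)
    ]
    seq = random_protein(rng, 60)
    pssm = single_sequence_pssm(seq)
    cal = calibrate_scores(pssm.scores, db, n_decoys=100, rng_seed=0)
    scores = np.linspace(cal.mu - 10, cal.mu + 60, 25)
    evalues = [cal.evalue(s, 10) for s in scores]
    assert all(a >= b for a, b in zip(evalues, evalues[1:]))
    assert np.isclose(cal.evalue(cal.mu + 5, 20), 2 * cal.evalue(cal.mu + 5, 10))


def test_pvalue_calibrated_on_fresh_decoys():
    """Monte-Carlo check of the fitted Gumbel tail: about 1% of fresh
    decoys reach the 0.01 p-value level (within half a point, averaged
    over three independent calibration/evaluation trials of 1000 decoys)."""
    from phyrn.profile import _decoy_scores
    from phyrn.profile_align import ProfileAligner

    fracs = []
    for trial in range(3):
        rng = np.random.default_rng(trial)
        db = [
            SequenceRecord(id=f"s{i}", residues=random_protein(rng, 150))
            for i in range(20)
        ]
        pssm = single_sequence_pssm(random_protein(rng, 80))
        cal = calibrate_scores(
            pssm.scores, db, n_decoys=1000, rng_seed=100 + trial
        )
        aligner = ProfileAligner(pssm.scores)
        fresh = _decoy_scores(aligner, db, 1000, np.random.default_rng(200 + trial))
        fracs.append(float(np.mean([cal.pvalue(s) <= 0.01 for s in fresh])))
    assert 0.005 <= float(np.mean(fracs)) <= 0.015


def test_conserved_family_argmax_recovers_ancestor():
    """At high conservation the enriched profile's per-column argmax is the
    ancestral residue for nearly every column."""
    fam = phyrn.simulate_family(
        phyrn.SimulationConfig(
            n_leaves=20,
            root_length=150,
            branch_length_mean=0.04,  # ~80% expected pairwise identity
            indel_rate=0.0,
            flank_length=20,
            rng_seed=11,
        )
    )
    seeds = phyrn.extract_domains(fam.leaf_records, fam.domain_boundaries)
    pssm = phyrn.build_pssm(
        seeds[0], fam.leaf_records, iterations=2, n_decoys=60, rng_seed=0
    )
    root = encode(fam.root_residues)
    argmax = pssm.scores.argmax(axis=1)
    recovered = float(np.mean(argmax == root))
    assert recovered >= 0.90


def test_library_save_load_roundtrip(tmp_path, small_library):
    small_library.save(tmp_path / "lib")
    back = phyrn.PSSMLibrary.load(tmp_path / "lib")
    assert back.ids == small_library.ids
    for a, b in zip(back, small_library):
        assert a.seed_residues == b.seed_residues
        assert np.allclose(a.scores, b.scores, atol=1e-6)
    assert back.build_params == small_library.build_params
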