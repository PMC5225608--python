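import numpy as np
import pytest

import cetevol as cv
from cetevol.alignment import CodonAlignment
from cetevol.genetics import BASES, CODON_INDEX, SENSE_CODONS
from cetevol.likelihood import (
    LikelihoodError,
    PruningEngine,
    build_rate_matrix,
    equal_frequencies,
    f3x4_frequencies,
    neutral_scaled_generator,
    transition_probabilities,
)
from cetevol.models import log_likelihood
from cetevol.phylo import parse_newick_labelled

from conftest import random_pi


# ---------------------------------------------------------------------------
# F3x4
# ---------------------------------------------------------------------------

def test_f3x4_uniform_composition_gives_uniform_pi():
    # each codon position sees every base exactly twice, and no stop codons
    seqs = ["ACACACGTGTGT", "AGCCTAGATTCG"]
    aln = CodonAlignment.from_sequences(["a", "b"], seqs)
    counts = np.zeros((3, 4))
    for name in aln.names:
        for s in range(aln.n_sites):
            codon = aln.codon_str(name, s)
            for p, b in enumerate(codon):
                counts[p, BASES.index(b)] += 1
    assert np.allclose(counts, 2)  # balanced by construction
    pi = f3x4_frequencies(aln)
    assert np.allclose(pi, 1 / 61)


def test_f3x4_forced_zero_when_base_absent():
    # third positions all G
    aln = CodonAlignment.from_sequences(["a", "b"], ["ATGGGG", "CTGAGG"])
    pi = f3x4_frequencies(aln)
    for c, p in zip(SENSE_CODONS, pi):
        if c[2] != "G":
            assert p == 0.0
    assert pi.sum() == pytest.approx(1.0)


def test_f3x4_matches_hand_counts_on_toy():
    """2-taxon, 4-codon toy against explicit per-position counting."""
    seqs = ["ATGGGTCATAAA", "ATGAGTCACAAG"]
    aln = CodonAlignment.from_sequences(["a", "b"], seqs)
    counts = [{b: 0 for b in BASES} for _ in range(3)]
    for seq in seqs:
        for i in range(0, 12, 3):
            for p in range(3):
                counts[p][seq[i + p]] += 1
    freqs = [{b: v / 8 for b, v in c.items()} for c in counts]
    expected = np.array(
        [freqs[0][c[0]] * freqs[1][c[1]] * freqs[2][c[2]] for c in SENSE_CODONS]
    )
    expected /= expected.sum()
    assert np.allclose(f3x4_frequencies(aln), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_rate_matrix_invariants(seed):
    """Rows sum to 0; detailed balance; unit mean rate, for random params."""
    rng = np.random.default_rng(seed)
    pi = random_pi(rng)
    kappa = float(rng.uniform(0.5, 8))
    omega = float(rng.uniform(0.05, 4))
    Q = build_rate_matrix(kappa, omega, pi)
    assert np.abs(Q.sum(axis=1)).max() < 1e-12
    flux = pi[:, None] * Q
    assert np.abs(flux - flux.T).max() < 1e-12  # reversibility
    assert -pi @ np.diag(Q) == pytest.approx(1.0, abs=1e-12)


def test_rate_matrix_multi_nucleotide_changes_zero():
    Q = build_rate_matrix(2.0, 0.5, equal_frequencies())
    assert Q[CODON_INDEX["AAA"], CODON_INDEX["ACC"]] == 0.0


def test_rate_matrix_uniform_neutral_symmetry():
    Q = build_rate_matrix(1.0, 1.0, equal_frequencies())
    off = Q[~np.eye(61, dtype=bool)]
    nz = off[off > 0]
    assert np.allclose(nz, nz[0])  # all single-step rates equal


def test_rate_ratio_is_kappa_over_omega():
    """TTT->TTC (syn transition) over TTT->TTA (nonsyn transversion)."""
    kappa, omega = 3.7, 0.21
    Q = build_rate_matrix(kappa, omega, equal_frequencies())
    i = CODON_INDEX["TTT"]
    ratio = Q[i, CODON_INDEX["TTC"]] / Q[i, CODON_INDEX["TTA"]]
    assert ratio == pytest.approx(kappa / omega, rel=1e-12)


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------

def _expm_series(Q, t, squarings=25, terms=20):
    """Independent scaling-and-squaring truncated-series matrix exponential."""
    A = Q * (t / 2.0**squarings)
    P = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms + 1):
        term = term @ A / k
        P = P + term
    for _ in range(squarings):
        P = P @ P
    return P


def test_transition_zero_time_is_identity():
    Q = build_rate_matrix(2.0, 0.5, equal_frequencies())
    P = transition_probabilities(Q, 0.0, equal_frequencies())
    assert np.allclose(P, np.eye(61), atol=1e-12)


def test_negative_time_rejected():
    Q = build_rate_matrix(2.0, 0.5, equal_frequencies())
    with pytest.raises(LikelihoodError):
        transition_probabilities(Q, -0.1, equal_frequencies())


@pytest.mark.parametrize("t", [0.05, 0.5, 2.0])
def test_transition_matches_series_oracle(t, rng):
    pi = random_pi(rng)
    kappa = float(rng.uniform(0.5, 6))
    omega = float(rng.uniform(0.05, 3))
    Q = build_rate_matrix(kappa, omega, pi)
    P = transition_probabilities(Q, t, pi)
    assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
    assert P.min() >= 0.0
    assert np.abs(P - _expm_series(Q, t)).max() < 1e-8


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _brute_force_loglik(aln, pi, kappa, omega, t):
    """Explicit enumeration over both internal-node states of
    ((A,B)u,C)root for each site; missing leaves marginalize to 1."""
    Q = neutral_scaled_generator(kappa, omega, pi)
    P = {k: transition_probabilities(Q, tk, pi) for k, tk in t.items()}
    total = 0.0
    for s in range(aln.n_sites):
        obs = {n: aln.matrix[aln.names.index(n), s] for n in ("A", "B", "C")}

        def leaf_factor(P_edge, u, leaf):
            state = obs[leaf]
            return 1.0 if state < 0 else P_edge[u, state]

        site = 0.0
        for r in range(61):
            inner = 0.0
            for u in range(61):
                inner += (
                    P["u"][r, u]
                    * leaf_factor(P["A"], u, "A")
                    * leaf_factor(P["B"], u, "B")
                )
            site += pi[r] * inner * leaf_factor(P["C"], r, "C")
        total += np.log(site)
    return total


def test_pruning_matches_brute_force_enumeration(rng):
    """3 taxa x 5 codons, including a gap column, vs explicit 61^2 sums."""
    tree = parse_newick_labelled("((A:0.12,B:0.31)u:0.2,C:0.4);")
    aln = CodonAlignment.from_sequences(
        ["A", "B", "C"],
        ["ATGGGTCATAAATTG", "ATGAGTCACAAG---", "ATGGGACATAAATTG"],
    )
    pi = random_pi(rng)
    kappa, omega = 2.3, 0.4
    t = {"A": 0.12, "B": 0.31, "C": 0.4, "u": 0.2}
    expected = _brute_force_loglik(aln, pi, kappa, omega, t)
    got = log_likelihood(
        aln, tree, kappa=kappa, site_classes=[(1.0, {0: omega})], pi=pi
    )
    assert got == pytest.approx(expected, abs=1e-8)


def test_zero_branch_lengths_give_stationary_loglik():
    tree = parse_newick_labelled("(A:0.0,B:0.0);")
    aln = CodonAlignment.from_sequences(["A", "B"], ["ATGGGT", "ATGGGT"])
    pi = equal_frequencies()
    got = log_likelihood(aln, tree, kappa=2.0, site_classes=[(1.0, {0: 0.5})], pi=pi)
    expected = sum(np.log(pi[aln.matrix[0, s]]) for s in range(aln.n_sites))
    assert got == pytest.approx(expected, abs=1e-10)


def test_likelihood_invariant_to_rerooting_and_leaf_order(rng):
    tree = parse_newick_labelled("(((A:0.1,B:0.2):0.15,C:0.3):0.05,D:0.4);")
    aln = CodonAlignment.from_sequences(
        ["A", "B", "C", "D"],
        ["ATGGGTCAT", "ATGAGTCAC", "ATGGGACAT", "TTGGGTCAT"],
    )
    pi = random_pi(rng)
    args = dict(kappa=1.9, site_classes=[(1.0, {0: 0.6})], pi=pi)
    base = log_likelihood(aln, tree, **args)
    rerooted = tree.rerooted(tree.mrca(["A", "B"]).name)
    assert log_likelihood(aln, rerooted, **args) == pytest.approx(base, abs=1e-9)
    perm = aln.take_taxa(["D", "B", "A", "C"])
    assert log_likelihood(perm, tree, **args) == pytest.approx(base, abs=1e-9)


def test_engine_rejects_taxon_mismatch():
    tree = parse_newick_labelled("(A:0.1,B:0.1);")
    aln = CodonAlignment.from_sequences(["A", "X"], ["ATG", "ATG"])
    with pytest.raises(LikelihoodError):
        PruningEngine(aln, tree, equal_frequencies())
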