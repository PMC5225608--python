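import numpy as np
import pytest

import cetevol as cv
from cetevol.alignment import CodonAlignment
from cetevol.ancestral import (
    AncestralError,
    AncestralStates,
    augment_with_ancestors,
    branch_replacements,
    marginal_ancestral_states,
)
from cetevol.genetics import CODON_INDEX, SENSE_CODONS
from cetevol.likelihood import edge_transition_matrices
from cetevol.models import fit_model
from cetevol.phylo import parse_newick_labelled


@pytest.fixture(scope="module")
def toy_fit():
    tree = parse_newick_labelled("((A:0.15,B:0.25)u:0.1,C:0.3);")
    aln = CodonAlignment.from_sequences(
        ["A", "B", "C"],
        ["ATGGGTCATAAATTG", "ATGAGTCACAAG---", "ATGGGACATAAATTG"],
    )
    fit = fit_model(aln, tree, "one-ratio", seed=0)
    return aln, fit


def test_marginal_posteriors_match_brute_force(toy_fit):
    """3-taxon toy: node posteriors vs explicit Bayes over 61^2 states."""
    aln, fit = toy_fit
    tree = fit.tree
    states = marginal_ancestral_states(aln, tree, fit)
    P = edge_transition_matrices(tree, fit.kappa, fit.site_classes[0][1], fit.pi)
    idx = {n.name: n.index for n in tree.postorder()}
    obs = {n: aln.row(n) for n in aln.names}
    pi = fit.pi
    for s in range(aln.n_sites):
        def leaf_f(leaf, u):
            state = obs[leaf][s]
            return 1.0 if state < 0 else P[idx[leaf]][u, state]

        joint = np.zeros((61, 61))  # root r x internal u
        for r in range(61):
            for u in range(61):
                joint[r, u] = (
                    pi[r]
                    * P[idx["u"]][r, u]
                    * leaf_f("A", u)
                    * leaf_f("B", u)
                    * leaf_f("C", r)
                )
        joint /= joint.sum()
        root_name = tree.root.name
        assert np.allclose(
            states.posteriors[root_name][s], joint.sum(axis=1), atol=1e-8
        )
        assert np.allclose(states.posteriors["u"][s], joint.sum(axis=0), atol=1e-8)


def test_posteriors_sum_to_one(toy_fit):
    aln, fit = toy_fit
    states = marginal_ancestral_states(aln, fit.tree, fit)
    for name in states.node_names:
        assert np.allclose(states.posteriors[name].sum(axis=1), 1.0, atol=1e-9)
        assert np.all(states.best_posterior[name] > 0)


def test_uniform_column_reconstructed_confidently():
    tree = parse_newick_labelled("((A:0.01,B:0.01):0.01,C:0.02);")
    aln = CodonAlignment.from_sequences(["A", "B", "C"], ["ATGCAT"] * 3)
    fit = fit_model(aln, tree, "one-ratio", seed=0, n_restarts=1)
    states = marginal_ancestral_states(aln, fit.tree, fit)
    for name in states.node_names:
        assert states.sequence_str(name) == "ATGCAT"
        assert np.all(states.best_posterior[name] > 0.99)


def test_simulation_truth_recovery(sim300, demo_tree, fit_m0):
    """>= 90% of internal states recovered on the 300-codon simulation."""
    aln, internal, _ = sim300
    states = marginal_ancestral_states(aln, fit_m0.tree, fit_m0)
    accs = []
    for name, truth in internal.items():
        accs.append(float((states.sequences[name] == truth).mean()))
    assert np.mean(accs) >= 0.90


def test_unfitted_model_rejected(sim300, demo_tree):
    aln, _, _ = sim300
    with pytest.raises(AncestralError):
        marginal_ancestral_states(aln, demo_tree, fit=None)


class TestAugment:
    def test_counts_and_content(self, sim300, demo_tree, fit_m0):
        aln, _, _ = sim300
        mrca = demo_tree.mrca(list(cv.simulate.CETACEANS))
        states = marginal_ancestral_states(aln, fit_m0.tree, fit_m0)
        aug, aug_tree = augment_with_ancestors(aln, fit_m0.tree, states, mrca.name)
        assert aug.n_taxa == 9  # 8 whales + 1 reconstructed MRCA
        assert set(aug_tree.leaf_names) == set(aug.names)
        anc_row = aug.row(mrca.name)
        assert np.array_equal(anc_row, states.sequences[mrca.name])

    def test_site_model_runs_on_augmented(self, sim300, demo_tree, fit_m0):
        aln, _, _ = sim300
        mrca = demo_tree.mrca(list(cv.simulate.CETACEANS))
        states = marginal_ancestral_states(aln, fit_m0.tree, fit_m0)
        aug, aug_tree = augment_with_ancestors(aln, fit_m0.tree, states, mrca.name)
        fit = fit_model(aug, aug_tree, "M1", seed=0, n_restarts=1)
        rec = fit.summary("SIMGENE")
        assert {"gene", "p0", "p1", "omega0", "lnL"} <= set(rec)

    def test_leaf_subtree_root_rejected(self, sim300, demo_tree, fit_m0):
        aln, _, _ = sim300
        states = marginal_ancestral_states(aln, fit_m0.tree, fit_m0)
        with pytest.raises(AncestralError):
            augment_with_ancestors(aln, fit_m0.tree, states, "fin_whale")


class TestBranchReplacements:
    def _toy(self):
        tree = parse_newick_labelled("((A:0.1,B:0.1)u:0.1,C:0.1);")
        tree.mark_clade(["A", "B"], 1, include_stem=True, name="cetacea")
        return tree

    def _states(self, tree, codons_by_node):
        seqs = {
            name: np.array([CODON_INDEX[c] for c in codons], dtype=np.int16)
            for name, codons in codons_by_node.items()
        }
        n = len(next(iter(codons_by_node.values())))
        post = {name: np.ones((n,)) for name in seqs}
        full = {name: np.full((n, 61), 1 / 61) for name in seqs}
        return AncestralStates(tuple(seqs), seqs, post, full)

    def test_identical_sequences_give_no_events(self):
        tree = self._toy()
        root = tree.root.name
        aln = CodonAlignment.from_sequences(["A", "B", "C"], ["GATGGT"] * 3)
        states = self._states(tree, {root: ["GAT", "GGT"], "u": ["GAT", "GGT"]})
        assert branch_replacements(states, aln, tree) == []

    def test_planted_replacement_on_stem(self):
        """D->G on the cetacean stem branch: exactly one event, right class."""
        tree = self._toy()
        root = tree.root.name
        # root/C carry GAT (Asp); the cetacean ancestor u and its leaves GGT (Gly)
        aln = CodonAlignment.from_sequences(["A", "B", "C"], ["GGT", "GGT", "GAT"])
        states = self._states(tree, {root: ["GAT"], "u": ["GGT"]})
        events = branch_replacements(states, aln, tree, gene="FGF9")
        assert len(events) == 1
        ev = events[0]
        assert (ev.ancestral, ev.derived) == ("D", "G")
        assert ev.branch == "u" and ev.branch_class == "cetacea"
        assert ev.position == 1

    def test_synonymous_change_emits_nothing(self):
        tree = self._toy()
        root = tree.root.name
        aln = CodonAlignment.from_sequences(["A", "B", "C"], ["GGC", "GGC", "GGT"])
        states = self._states(tree, {root: ["GGT"], "u": ["GGC"]})
        events = branch_replacements(states, aln, tree)
        assert events == []

    def test_events_invariant_to_leaf_order(self, sim300, demo_tree, fit_m0):
        aln, _, _ = sim300
        states = marginal_ancestral_states(aln, fit_m0.tree, fit_m0)
        ev1 = branch_replacements(states, aln, fit_m0.tree)
        shuffled = aln.take_taxa(list(aln.names)[::-1])
        ev2 = branch_replacements(states, shuffled, fit_m0.tree)
        key = lambda e: (e.branch, e.position, e.ancestral, e.derived)
        assert sorted(map(key, ev1)) == sorted(map(key, ev2))
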