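"""Marginal ML ancestral codon reconstruction and replacement extraction.

Reconstruction is marginal (per node, per site): the posterior of a codon at
an internal node is proportional to the product of the upward (inside) and
downward (outside) partial likelihoods, with the equilibrium frequencies
entering at the root.  Under a site-class mixture the per-class posteriors
are averaged with the NEB class-membership weights.  Ties are broken toward
the lowest codon index by the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.special

from .alignment import MISSING, CodonAlignment
from .genetics import N_CODONS, SENSE_CODONS, GeneticCode
from .likelihood import PruningEngine, edge_transition_matrices
from .models import FitResult
from .phylo import Node, Phylogeny


class AncestralError(ValueError):
    pass


@dataclass
class AncestralStates:
    """Reconstructed codon states at the internal nodes of one tree."""

    node_names: tuple[str, ...]
    sequences: dict[str, np.ndarray]  # name -> (n_sites,) codon indices
    best_posterior: dict[str, np.ndarray]  # name -> (n_sites,) prob of chosen state
    posteriors: dict[str, np.ndarray]  # name -> (n_sites, 61)

    def sequence_str(self, name: str) -> str:
        return "".join(SENSE_CODONS[s] for s in self.sequences[name])


@dataclass(frozen=True)
class ReplacementEvent:
    """One amino-acid replacement assigned to a branch."""

    gene: str
    position: int  # 1-based amino-acid coordinate in the alignment
    ancestral: str
    derived: str
    branch: str  # child-node name of the edge
    branch_class: str
    ref_position: int | None = None  # 1-based reference-protein coordinate


def _class_posteriors(engine: PruningEngine, fit: FitResult) -> np.ndarray:
    """(n_classes, n_patterns) NEB weights; degenerate classes get 0."""
    cond = engine.class_pattern_log_likelihoods(fit.kappa, fit.site_classes)
    w = np.array([max(p, 0.0) for p, _ in fit.site_classes])
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    joint = cond + logw[:, None]
    q = np.exp(joint - scipy.special.logsumexp(joint, axis=0)[None, :])
    q[w == 0.0, :] = 0.0
    return q / q.sum(axis=0, keepdims=True)


def _node_posteriors_one_class(
    engine: PruningEngine,
    P_by_edge: dict[int, np.ndarray],
) -> dict[int, np.ndarray]:
    """Marginal posteriors per internal node for a single omega class."""
    tree = engine.tree
    inside, _ = engine.inside_partials(P_by_edge)
    outside: dict[int, np.ndarray] = {
        tree.root.index: np.broadcast_to(engine.pi, (engine.n_patterns, N_CODONS)).copy()
    }
    post: dict[int, np.ndarray] = {}
    for node in reversed(tree.postorder()):  # preorder
        if node.is_leaf:
            continue
        out = outside[node.index]
        joint = out * inside[node.index]
        norm = joint.sum(axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        post[node.index] = joint / norm
        msgs = {
            c.index: inside[c.index] @ P_by_edge[c.index].T for c in node.children
        }
        for child in node.children:
            if child.is_leaf:
                continue
            tmp = out.copy()
            for sib in node.children:
                if sib is not child:
                    tmp = tmp * msgs[sib.index]
            o = tmp @ P_by_edge[child.index]
            s = o.max(axis=1, keepdims=True)
            s[s == 0.0] = 1.0
            outside[child.index] = o / s
    return post


def marginal_ancestral_states(
    alignment: CodonAlignment,
    tree: Phylogeny,
    fit: FitResult,
) -> AncestralStates:
    """Marginal (CODEML-style) reconstruction under a fitted codon model."""
    if not isinstance(fit, FitResult):
        raise AncestralError("a fitted model (FitResult) is required")
    engine = PruningEngine(alignment, tree, fit.pi)
    q = _class_posteriors(engine, fit)
    combined: dict[int, np.ndarray] = {}
    for c, (_, omega_map) in enumerate(fit.site_classes):
        if np.all(q[c] == 0.0):
            continue
        P = edge_transition_matrices(tree, fit.kappa, omega_map, fit.pi)
        post_c = _node_posteriors_one_class(engine, P)
        for idx, p in post_c.items():
            acc = combined.setdefault(idx, np.zeros_like(p))
            acc += q[c][:, None] * p
    names, seqs, best, full = [], {}, {}, {}
    for node in tree.postorder():
        if node.is_leaf:
            continue
        p = engine.expand(combined[node.index].T).T  # (n_sites, 61)
        states = p.argmax(axis=1)
        names.append(node.name)
        seqs[node.name] = states.astype(np.int16)
        best[node.name] = p[np.arange(p.shape[0]), states]
        full[node.name] = p
    return AncestralStates(tuple(names), seqs, best, full)


def augment_with_ancestors(
    alignment: CodonAlignment,
    tree: Phylogeny,
    states: AncestralStates,
    subtree_root: str,
    *,
    include_all_ancestors: bool = False,
) -> tuple[CodonAlignment, Phylogeny]:
    """Extant subtree sequences plus reconstructed ancestor(s) as extra rows.

    The subtree's reconstructed root sequence (and optionally every internal
    node of the subtree) is appended as a tip, yielding the whale-style
    extant+ancestral alignment used for downstream site-model and per-site
    selection analyses.
    """
    src = tree.node(subtree_root)
    if src.is_leaf:
        raise AncestralError("subtree root must be an internal node")
    sub = tree.subtree(subtree_root)
    anc_names = [subtree_root]
    if include_all_ancestors:
        anc_names += [
            n.name
            for n in sub.postorder()
            if not n.is_leaf and n.name != subtree_root and n.name in states.sequences
        ]
    leaf_names = sub.leaf_names
    rows = [alignment.row(n) for n in leaf_names]
    rows += [states.sequences[a] for a in anc_names]
    matrix = np.vstack(rows).astype(np.int16)
    out_aln = CodonAlignment(tuple(leaf_names) + tuple(anc_names), matrix)

    # rename internal nodes so the appended ancestor tips keep their ids
    new_tree = sub.copy()
    for i, n in enumerate(new_tree.postorder()):
        if not n.is_leaf:
            n.name = f"n{i}"
    for a in anc_names:
        tip = Node(a, 0.0, new_tree.root.children[0].cls if new_tree.root.children else 0)
        new_tree.root.add(tip)
    return out_aln, Phylogeny(new_tree.root, tree.class_names)


def branch_replacements(
    states: AncestralStates,
    alignment: CodonAlignment,
    tree: Phylogeny,
    code: GeneticCode | None = None,
    *,
    gene: str = "",
    ref_positions: dict[int, int] | None = None,
) -> list[ReplacementEvent]:
    """Amino-acid replacements per edge from reconstructed + extant codons.

    Synonymous codon changes emit nothing; sites missing in either endpoint
    are skipped.  ``ref_positions`` optionally maps 1-based alignment
    positions to reference-protein coordinates.
    """
    code = code or GeneticCode.standard()
    events: list[ReplacementEvent] = []
    for edge in tree.edges():
        parent = edge.parent
        assert parent is not None
        parent_seq = states.sequences[parent.name]
        child_seq = (
            alignment.row(edge.name) if edge.is_leaf else states.sequences[edge.name]
        )
        cls_label = tree.class_names.get(edge.cls, str(edge.cls))
        for s in range(len(parent_seq)):
            a, d = int(parent_seq[s]), int(child_seq[s])
            if a == MISSING or d == MISSING or a == d:
                continue
            aa_a = code.translate_codon(SENSE_CODONS[a])
            aa_d = code.translate_codon(SENSE_CODONS[d])
            if aa_a == aa_d:
                continue
            events.append(
                ReplacementEvent(
                    gene=gene,
                    position=s + 1,
                    ancestral=aa_a,
                    derived=aa_d,
                    branch=edge.name,
                    branch_class=cls_label,
                    ref_position=None if ref_positions is None else ref_positions.get(s + 1),
                )
            )
    return events
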