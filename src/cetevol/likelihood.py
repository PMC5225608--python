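"""Goldman-Yang codon substitution likelihood engine.

The instantaneous rate between codons differing at exactly one nucleotide is
proportional to the target codon's equilibrium frequency, multiplied by the
transition/transversion ratio kappa for transitions and by omega (dN/dS) for
nonsynonymous changes.  Rates between codons differing at more than one
position are zero.  Q is scaled so the expected number of substitutions per
codon per unit branch length is one, which makes branch lengths directly
comparable across parameter values.

Phylogenetic likelihoods use Felsenstein pruning with per-node scaling; the
model is time-reversible, so the likelihood does not depend on root placement.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.special

from .alignment import MISSING, CodonAlignment
from .genetics import BASES, N_CODONS, SENSE_CODONS, codon_change_tables
from .phylo import Phylogeny

_MIN_PI = 0.0


class LikelihoodError(ValueError):
    pass


# ---------------------------------------------------------------------------
# equilibrium frequencies
# ---------------------------------------------------------------------------

def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    pi_c is proportional to the product of the three position-specific
    nucleotide frequencies of codon c, renormalized over the 61 sense
    codons.  Gap/ambiguous codons contribute nothing.
    """
    counts = np.zeros((3, 4))
    base_index = {b: k for k, b in enumerate(BASES)}
    observed = alignment.matrix[alignment.matrix != MISSING]
    if observed.size == 0:
        raise LikelihoodError("no observable codons")
    for state in observed:
        codon = SENSE_CODONS[state]
        for p in range(3):
            counts[p, base_index[codon[p]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, base_index[c[0]]]
            * freqs[1, base_index[c[1]]]
            * freqs[2, base_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise LikelihoodError("degenerate F3x4 frequencies")
    return pi / total


def f61_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Observed sense-codon frequencies (F61), renormalized."""
    observed = alignment.matrix[alignment.matrix != MISSING]
    if observed.size == 0:
        raise LikelihoodError("no observable codons")
    counts = np.bincount(observed, minlength=N_CODONS).astype(float)
    return counts / counts.sum()


def equal_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def codon_frequencies(alignment: CodonAlignment, scheme: str = "F3x4") -> np.ndarray:
    scheme = scheme.upper()
    if scheme == "F3X4":
        return f3x4_frequencies(alignment)
    if scheme == "F61":
        return f61_frequencies(alignment)
    if scheme == "EQUAL":
        return equal_frequencies()
    raise ValueError(f"unknown frequency scheme '{scheme}'")


def _check_pi(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise LikelihoodError("invalid codon frequency vector")
    return pi


# ---------------------------------------------------------------------------
# rate matrix and propagators
# ---------------------------------------------------------------------------

def syn_nonsyn_parts(kappa: float, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal synonymous/nonsynonymous GY94 parts (A, B), jointly
    scaled so the neutral generator A + B has unit mean rate.

    ``A + omega * B`` (diagonal filled) is then the generator whose branch
    lengths are in expected substitutions per codon under neutrality; an
    omega > 1 site class genuinely evolves faster, as it should.
    """
    if kappa <= 0:
        raise LikelihoodError("kappa must be positive")
    pi = _check_pi(pi)
    ndiff, trans, nonsyn, _ = codon_change_tables()
    single = ndiff == 1
    mult = np.where(trans, kappa, 1.0) * pi[None, :]
    A = np.where(single & ~nonsyn, mult, 0.0)
    B = np.where(single & nonsyn, mult, 0.0)
    rate = float(pi @ (A + B).sum(axis=1))
    if rate <= 0:
        raise LikelihoodError("rate matrix has zero mean rate; check pi")
    return A / rate, B / rate


def neutral_scaled_generator(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 generator A + omega*B on the neutral branch-length scale."""
    if omega < 0:
        raise LikelihoodError("omega must be non-negative")
    A, B = syn_nonsyn_parts(kappa, pi)
    Q = A + omega * B
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 rate matrix normalized to one expected substitution per unit t."""
    if omega < 0:
        raise LikelihoodError("omega must be non-negative")
    pi = _check_pi(pi)
    Q = neutral_scaled_generator(kappa, omega, pi)
    rate = -float(pi @ np.diag(Q))
    if rate <= 0:
        raise LikelihoodError("rate matrix has zero mean rate; check pi")
    return Q / rate


def eig_rate_matrix(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of Q via the reversibility-symmetrized matrix.

    Valid for strictly positive pi (the reversible case); returns
    ``(U, lam, Uinv)`` with ``Q = U diag(lam) Uinv``.  Falls back to None
    when pi has zeros, in which case callers use ``expm`` directly.
    """
    if np.any(pi <= 0):
        return None
    sqrt_pi = np.sqrt(pi)
    # detailed balance makes pi^{1/2} Q pi^{-1/2} symmetric
    S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    S = (S + S.T) / 2.0  # shed floating-point asymmetry only
    lam, V = np.linalg.eigh(S)
    U = V / sqrt_pi[:, None]  # Q = (pi^{-1/2} V) diag(lam) (V^T pi^{1/2})
    Uinv = V.T * sqrt_pi[None, :]
    return U, lam, Uinv


def transition_probabilities(
    Q: np.ndarray,
    t: float,
    pi: np.ndarray | None = None,
    eig=None,
) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to one, tiny negatives clipped to zero."""
    if t < 0:
        raise LikelihoodError("branch length must be non-negative")
    if eig is None and pi is not None:
        eig = eig_rate_matrix(Q, np.asarray(pi, dtype=float))
    if eig is not None:
        U, lam, Uinv = eig
        P = (U * np.exp(lam * t)[None, :]) @ Uinv
    else:
        P = scipy.linalg.expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def edge_transition_matrices(
    tree: Phylogeny,
    kappa: float,
    omega_by_class: dict[int, float],
    pi: np.ndarray,
) -> dict[int, np.ndarray]:
    """P(t_e) per edge (keyed by node index) for a branch-class omega map.

    Generators are on the neutral branch-length scale (see
    :func:`syn_nonsyn_parts`).  One eigendecomposition per distinct omega
    value; edges then only cost a matrix reconstruction.
    """
    eigs = {
        w: eig_rate_matrix(neutral_scaled_generator(kappa, w, pi), pi)
        for w in set(omega_by_class.values())
    }
    out: dict[int, np.ndarray] = {}
    for edge in tree.edges():
        w = omega_by_class[edge.cls]
        eig = eigs[w]
        if eig is None:
            Q = neutral_scaled_generator(kappa, w, pi)
            out[edge.index] = transition_probabilities(Q, edge.length)
        else:
            out[edge.index] = transition_probabilities(None, edge.length, eig=eig)
    return out


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

class PruningEngine:
    """Felsenstein pruning over compressed site patterns.

    The engine is bound to one alignment/tree pair; transition matrices are
    supplied per call so one engine serves a whole optimization.
    """

    def __init__(self, alignment: CodonAlignment, tree: Phylogeny, pi: np.ndarray):
        missing = set(tree.leaf_names) ^ set(alignment.names)
        if set(alignment.names) - set(tree.leaf_names):
            raise LikelihoodError(
                f"alignment taxa absent from tree: "
                f"{sorted(set(alignment.names) - set(tree.leaf_names))}"
            )
        extra = set(tree.leaf_names) - set(alignment.names)
        if extra:
            raise LikelihoodError(f"tree leaves absent from alignment: {sorted(extra)}")
        del missing
        self.tree = tree
        self.pi = _check_pi(pi)
        cols, weights, inverse = alignment.patterns()
        self.n_patterns = cols.shape[1]
        self.weights = weights
        self.site_to_pattern = inverse
        self.n_sites = alignment.n_sites
        order = [alignment.names.index(leaf.name) for leaf in tree.leaves()]
        self._leaf_partials: dict[int, np.ndarray] = {}
        for leaf, row_idx in zip(tree.leaves(), order):
            states = cols[row_idx]
            L = np.zeros((self.n_patterns, N_CODONS))
            obs = states != MISSING
            L[np.arange(self.n_patterns)[obs], states[obs]] = 1.0
            L[~obs] = 1.0
            self._leaf_partials[leaf.index] = L

    def inside_partials(
        self, P_by_edge: dict[int, np.ndarray]
    ) -> tuple[dict[int, np.ndarray], np.ndarray]:
        """Scaled inside (upward) partials per node and per-pattern log-lik."""
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_patterns)
        for node in self.tree.postorder():
            if node.is_leaf:
                partial[node.index] = self._leaf_partials[node.index]
                continue
            L = np.ones((self.n_patterns, N_CODONS))
            for child in node.children:
                L = L * (partial[child.index] @ P_by_edge[child.index].T)
            scale = L.max(axis=1)
            scale[scale == 0.0] = 1.0
            L /= scale[:, None]
            logscale += np.log(scale)
            partial[node.index] = L
        root_L = partial[self.tree.root.index] @ self.pi
        with np.errstate(divide="ignore"):
            return partial, np.log(root_L) + logscale

    def pattern_log_likelihoods(self, P_by_edge: dict[int, np.ndarray]) -> np.ndarray:
        """log-likelihood per site pattern for one set of edge propagators."""
        return self.inside_partials(P_by_edge)[1]

    def class_pattern_log_likelihoods(
        self,
        kappa: float,
        site_classes: list[tuple[float, dict[int, float]]],
    ) -> np.ndarray:
        """(n_classes, n_patterns) conditional log-likelihoods.

        ``site_classes`` lists (weight, omega-by-branch-class) pairs; weights
        are not applied here.
        """
        out = np.empty((len(site_classes), self.n_patterns))
        for c, (_, omega_map) in enumerate(site_classes):
            P = edge_transition_matrices(self.tree, kappa, omega_map, self.pi)
            out[c] = self.pattern_log_likelihoods(P)
        return out

    def mixture_log_likelihood(
        self,
        kappa: float,
        site_classes: list[tuple[float, dict[int, float]]],
    ) -> float:
        """Total log-likelihood with per-site marginalization over classes."""
        cond = self.class_pattern_log_likelihoods(kappa, site_classes)
        w = np.array([max(wc, 0.0) for wc, _ in site_classes])
        with np.errstate(divide="ignore"):
            logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
        site_log = scipy.special.logsumexp(cond + logw[:, None], axis=0)
        return float(self.weights @ site_log)

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map per-pattern values back onto alignment sites (last axis)."""
        return np.take(per_pattern, self.site_to_pattern, axis=-1)
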