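"""Synthetic-data generation: codon alignments evolved along a phylogeny,
lineage-targeted ORF disruptions, and promoter sets with planted HREs.

Sequence evolution samples endpoint states exactly from the transition
matrix of each branch (no intermediate-event simulation is needed because
only node states are observed).  All generators are seed-deterministic and
return machine-readable truth sets for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment import CodonAlignment
from .genetics import N_CODONS
from .likelihood import equal_frequencies
from .phylo import Phylogeny, parse_newick_labelled
from .pseudogene import DisruptionEvent

CETACEANS = (
    "fin_whale",
    "minke_whale",
    "bowhead_whale",
    "sperm_whale",
    "killer_whale",
    "bottlenose_dolphin",
    "finless_porpoise",
    "baiji",
)
PRIMATES = ("human", "chimpanzee", "macaque")
ARTIODACTYLS = ("cow", "pig", "sheep")

# 8 cetaceans + 4 outgroups; baleen/toothed split inside the whale clade,
# artiodactyl sister group, primate+rodent outgroups; lengths ~0.01-0.1
# expected substitutions per codon.
_DEMO_NEWICK = (
    "((("
    "((fin_whale:0.010,minke_whale:0.012):0.012,bowhead_whale:0.020):0.015,"
    "(((bottlenose_dolphin:0.012,killer_whale:0.012):0.010,"
    "finless_porpoise:0.020):0.012,"
    "(baiji:0.025,sperm_whale:0.030):0.008):0.012"
    "):0.050,"
    "(cow:0.070,pig:0.075):0.030):0.020,"
    "(human:0.090,mouse:0.100):0.040);"
)


def demo_tree(*, mark_whales: bool = True) -> Phylogeny:
    """The packaged 12-taxon demo phylogeny (8 cetaceans + 4 outgroups).

    With ``mark_whales`` the whale clade, including its stem branch, is
    painted branch class 1 ("whales"); everything else stays class 0.
    """
    tree = parse_newick_labelled(_DEMO_NEWICK)
    if mark_whales:
        tree.mark_clade(list(CETACEANS), 1, include_stem=True, name="whales")
        tree.class_names[0] = "background"
    return tree


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    """Everything needed to simulate one codon alignment."""

    tree: Phylogeny
    length: int
    seed: int
    kappa: float = 2.0
    pi: np.ndarray | None = None  # default: equal sense-codon frequencies
    omega: float | dict[int, float] | None = None  # branch(-class) regime
    # entries: (weight, omega-or-map) or (weight, omega-or-map, rate-or-map);
    # the optional rate multiplies branch lengths for sites of that class
    # (an episodic burst elevates the substitution rate, not only omega)
    site_classes: list[tuple] | None = None

    def normalized_classes(self) -> list[tuple[float, dict[int, float], dict[int, float]]]:
        bcls = sorted({e.cls for e in self.tree.edges()})

        def as_map(w) -> dict[int, float]:
            if isinstance(w, dict):
                missing = set(bcls) - set(w)
                if missing:
                    raise SimulationError(f"omega map misses branch classes {missing}")
                return {b: float(w[b]) for b in bcls}
            return {b: float(w) for b in bcls}

        if self.site_classes is not None:
            classes = []
            for entry in self.site_classes:
                p, w = entry[0], entry[1]
                rate = entry[2] if len(entry) > 2 else 1.0
                classes.append((float(p), as_map(w), as_map(rate)))
        elif self.omega is not None:
            classes = [(1.0, as_map(self.omega), as_map(1.0))]
        else:
            raise SimulationError("specify either omega or site_classes")
        total = sum(p for p, _, _ in classes)
        if not np.isclose(total, 1.0, atol=1e-9) or any(p < 0 for p, _, _ in classes):
            raise SimulationError("site-class weights must be non-negative and sum to 1")
        if self.length < 1:
            raise SimulationError("length must be >= 1 codon")
        if self.kappa <= 0:
            raise SimulationError("kappa must be positive")
        return classes


def _sample_rows(P: np.ndarray, parents: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of child states given parent states."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    return (cum[parents] < u[:, None]).sum(axis=1).astype(np.int16)


def simulate_codon_alignment(
    spec: SimulationSpec,
) -> tuple[CodonAlignment, dict[str, np.ndarray], np.ndarray]:
    """Evolve codons along the tree; returns (alignment, node states, classes).

    Site classes are drawn once (at the root) per site; each branch then uses
    its class-specific omega.  The truth set contains every node's states.
    """
    classes = spec.normalized_classes()
    pi = equal_frequencies() if spec.pi is None else np.asarray(spec.pi, float)
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    site_class = rng.choice(len(classes), size=n, p=[p for p, _, _ in classes])
    states: dict[str, np.ndarray] = {}
    tree = spec.tree
    root_states = rng.choice(N_CODONS, size=n, p=pi).astype(np.int16)
    states[tree.root.name] = root_states
    from .likelihood import (
        eig_rate_matrix,
        neutral_scaled_generator,
        transition_probabilities,
    )

    P_per_class = []
    for _, omega_map, rate_map in classes:
        eigs = {
            w: eig_rate_matrix(neutral_scaled_generator(spec.kappa, w, pi), pi)
            for w in set(omega_map.values())
        }
        per_edge = {
            e.index: transition_probabilities(
                None, e.length * rate_map[e.cls], eig=eigs[omega_map[e.cls]]
            )
            for e in tree.edges()
        }
        P_per_class.append(per_edge)
    for node in reversed(tree.postorder()):  # preorder: parents first
        if node is tree.root:
            continue
        parent_states = states[node.parent.name]
        child = np.empty(n, dtype=np.int16)
        u = rng.random(n)
        for c in range(len(classes)):
            mask = site_class == c
            if not mask.any():
                continue
            P = P_per_class[c][node.index]
            child[mask] = _sample_rows(P, parent_states[mask], u[mask])
        states[node.name] = child
    leaf_names = tuple(tree.leaf_names)
    matrix = np.vstack([states[nm] for nm in leaf_names])
    alignment = CodonAlignment(leaf_names, matrix)
    internal = {
        nm: arr for nm, arr in states.items() if nm not in alignment.names
    }
    return alignment, internal, site_class


# ---------------------------------------------------------------------------
# disruption injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisruptionPlan:
    taxon: str
    kind: str  # nonsense | frameshift-insertion | frameshift-deletion | exon-loss
    position: int  # codon position (nonsense/frameshift) or exon index (exon-loss)
    length: int = 0  # indel length in nucleotides


def inject_disruptions(
    rows: Sequence[tuple[str, str]],
    plan: Sequence[DisruptionPlan | tuple],
    exons: Sequence[tuple[int, int]] | None = None,
) -> tuple[list[tuple[str, str]], list[DisruptionEvent]]:
    """Edit an aligned nucleotide alignment and return the expected events.

    The input alignment must be gap-free (the usual case: a simulated
    alignment); insertions add columns, so all rows stay equal length.
    """
    plans = [p if isinstance(p, DisruptionPlan) else DisruptionPlan(*p) for p in plan]
    rows = [(n, s.upper()) for n, s in rows]
    names = [n for n, _ in rows]
    for p in plans:
        if p.taxon not in names:
            raise SimulationError(f"unknown taxon '{p.taxon}'")
        if p.kind.startswith("frameshift") and p.length % 3 == 0:
            raise SimulationError(
                f"frameshift length must not be divisible by 3 (got {p.length})"
            )
        if p.kind == "exon-loss" and exons is None:
            raise SimulationError("exon-loss injection needs an exon map")

    grid = {n: list(s) for n, s in rows}
    length = len(rows[0][1])
    expected: list[DisruptionEvent] = []

    def nt_of(p: DisruptionPlan) -> int:
        if p.kind == "exon-loss":
            return exons[p.position - 1][0]
        return (p.position - 1) * 3

    # in-place edits first (original reference coordinates stay valid), then
    # insertions from right to left so earlier columns never shift
    ordered = [p for p in plans if p.kind != "frameshift-insertion"] + sorted(
        (p for p in plans if p.kind == "frameshift-insertion"),
        key=nt_of,
        reverse=True,
    )
    for p in ordered:
        if p.kind == "nonsense":
            nt = (p.position - 1) * 3
            if nt + 3 > length:
                raise SimulationError("nonsense position beyond sequence end")
            grid[p.taxon][nt : nt + 3] = list("TGA")
            expected.append(
                DisruptionEvent(
                    taxon=p.taxon, kind="nonsense", position=p.position, stop_codon="TGA"
                )
            )
        elif p.kind == "frameshift-deletion":
            nt = (p.position - 1) * 3
            if nt + p.length > length:
                raise SimulationError("deletion extends beyond sequence end")
            for i in range(nt, nt + p.length):
                grid[p.taxon][i] = "-"
            expected.append(
                DisruptionEvent(
                    taxon=p.taxon,
                    kind="frameshift-deletion",
                    position=p.position,
                    length=p.length,
                )
            )
        elif p.kind == "frameshift-insertion":
            nt = (p.position - 1) * 3
            for name in grid:
                filler = "C" * p.length if name == p.taxon else "-" * p.length
                grid[name][nt:nt] = list(filler)
            expected.append(
                DisruptionEvent(
                    taxon=p.taxon,
                    kind="frameshift-insertion",
                    position=p.position,
                    length=p.length,
                )
            )
        elif p.kind == "exon-loss":
            a, b = exons[p.position - 1]
            for i in range(a, min(b, length)):
                grid[p.taxon][i] = "-"
            expected.append(
                DisruptionEvent(
                    taxon=p.taxon,
                    kind="exon-loss",
                    position=a // 3 + 1,
                    exon=p.position,
                )
            )
        else:
            raise SimulationError(f"unknown disruption kind '{p.kind}'")
        length = len(next(iter(grid.values())))

    out = [(n, "".join(grid[n])) for n, _ in rows]
    return out, expected


# ---------------------------------------------------------------------------
# promoter simulation
# ---------------------------------------------------------------------------

DEFAULT_PROMOTER_CLADES: dict[str, tuple[str, ...]] = {
    "cetacea": CETACEANS,
    "primates": PRIMATES,
    "artiodactyla": ARTIODACTYLS,
}

_HRE = "ACGTG"


def _scrub(seq: list[str], allowed_starts: set[int], rng: np.random.Generator) -> None:
    """Destroy every non-planted HRE occurrence in place."""
    s = "".join(seq)
    guard = 0
    while True:
        dirty = [
            i
            for i in range(len(s) - 4)
            if s[i : i + 5] == _HRE and i not in allowed_starts
        ]
        if not dirty:
            return
        for i in dirty:
            # flip the middle base; never touches a planted window because
            # planted windows are spaced >= 1 column apart from anything else
            seq[i + 2] = "C" if seq[i + 2] != "C" else "T"
        s = "".join(seq)
        guard += 1
        if guard > 50:  # pragma: no cover - safety valve
            raise SimulationError("could not scrub incidental motifs")


def simulate_promoters(
    clades: dict[str, Sequence[str]] | None = None,
    planted: Sequence[tuple[str, int]] = (),
    length: int = 2000,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, int], dict[str, set[int]]]:
    """Aligned promoter rows with planted, clade-structured HRE groups.

    ``planted`` lists (clade-name-or-"all", group count) pairs; each group is
    one homologous column window carrying ACGTG in every member of that clade
    (or all species) and in no one else.  Background sequence is scrubbed of
    incidental motifs.  Returns (rows, expected per-clade counts, the planted
    start columns per species).
    """
    clades = {k: tuple(v) for k, v in (clades or DEFAULT_PROMOTER_CLADES).items()}
    species = [sp for members in clades.values() for sp in members]
    if len(set(species)) != len(species):
        raise SimulationError("species assigned to two clades")
    n_groups = sum(c for _, c in planted)
    if length < n_groups * 7 + 10:
        raise SimulationError("promoter length too short for requested motifs")
    rng = np.random.default_rng(seed)
    rows = {
        sp: list("".join(rng.choice(list("ACGT"), size=length))) for sp in species
    }
    # evenly spaced, non-adjacent 5-column windows
    slots = np.linspace(2, length - 7, max(n_groups, 1)).astype(int) if n_groups else []
    truth = {clade: 0 for clade in clades}
    truth["all-species"] = 0
    allowed: dict[str, set[int]] = {sp: set() for sp in species}
    gi = 0
    for target, count in planted:
        if target != "all" and target not in clades:
            raise SimulationError(f"unknown clade '{target}'")
        members = species if target == "all" else list(clades[target])
        for _ in range(count):
            start = int(slots[gi])
            gi += 1
            for sp in species:
                if sp in members:
                    rows[sp][start : start + 5] = list(_HRE)
                    allowed[sp].add(start)
                else:
                    # make sure non-members cannot match at this window
                    rows[sp][start + 2] = "C" if rows[sp][start + 2] != "C" else "T"
            if target == "all":
                truth["all-species"] += 1
            else:
                truth[target] += 1
    for sp in species:
        _scrub(rows[sp], allowed[sp], rng)
    return [(sp, "".join(rows[sp])) for sp in species], truth, allowed
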