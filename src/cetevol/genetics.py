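"""Standard genetic code utilities for codon-model work.

The codon state space used throughout the package is the 61 sense codons of
the standard (universal) genetic code, ordered alphabetically over the bases
A < C < G < T.  Stop codons (TAA, TAG, TGA) are excluded from the likelihood
state space; they only appear in the pseudogene scanner, which works on raw
nucleotide alignments.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)
N_CODONS = len(SENSE_CODONS)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS: tuple[str, ...] = tuple(
    _STANDARD.forward_table[c] for c in SENSE_CODONS
)


class GeneticCode:
    """The standard genetic code over the 61-sense-codon state space."""

    def __init__(self) -> None:
        self.sense_codons = SENSE_CODONS
        self.stop_codons = STOP_CODONS
        self.codon_index = CODON_INDEX
        self.amino_acids = AMINO_ACIDS

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls()

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in STOP_CODONS

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid for a sense codon; '*' for stops."""
        codon = codon.upper()
        if codon in STOP_CODONS:
            return "*"
        return AMINO_ACIDS[CODON_INDEX[codon]]

    def translate(self, seq: str) -> str:
        """Translate an in-frame nucleotide string; gaps/ambiguity give 'X'."""
        out = []
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3].upper()
            if codon in STOP_CODONS:
                out.append("*")
            elif codon in CODON_INDEX:
                out.append(AMINO_ACIDS[CODON_INDEX[codon]])
            else:
                out.append("X")
        return "".join(out)

    def is_synonymous(self, c1: str, c2: str) -> bool:
        return self.translate_codon(c1) == self.translate_codon(c2)


def is_transition(b1: str, b2: str) -> bool:
    """A<->G or C<->T single-base change."""
    return b1 != b2 and (
        {b1, b2} <= PURINES or {b1, b2} <= PYRIMIDINES
    )


@lru_cache(maxsize=1)
def codon_change_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise 61x61 structure of single-nucleotide codon changes.

    Returns ``(ndiff, transition, nonsynonymous, diff_pos)`` where ``ndiff``
    counts differing nucleotide positions, ``transition`` and
    ``nonsynonymous`` are boolean and only meaningful where ``ndiff == 1``,
    and ``diff_pos`` is the differing position (0..2, or -1).
    """
    n = N_CODONS
    ndiff = np.zeros((n, n), dtype=np.int8)
    trans = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    dpos = np.full((n, n), -1, dtype=np.int8)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            ndiff[i, j] = len(diffs)
            if len(diffs) == 1:
                p = diffs[0]
                dpos[i, j] = p
                trans[i, j] = is_transition(ci[p], cj[p])
                nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return ndiff, trans, nonsyn, dpos
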