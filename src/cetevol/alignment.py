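"""In-frame codon alignments.

A :class:`CodonAlignment` is a taxa-by-codon-site matrix over the 61 sense
codons, with gaps and IUPAC-ambiguous codons treated as missing data.  For
likelihood work in-frame stop codons are an input error (the pseudogene
scanner deliberately bypasses this container and reads raw nucleotide
alignments instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import CODON_INDEX, SENSE_CODONS, STOP_CODONS, GeneticCode

MISSING = -1


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class CodonAlignment:
    """Ordered taxa and their codon-state sequences.

    ``matrix`` holds the sense-codon index per taxon and site, with
    :data:`MISSING` (-1) for gap or ambiguous codons.
    """

    names: tuple[str, ...]
    matrix: np.ndarray  # (n_taxa, n_sites) int16

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise AlignmentError("matrix shape does not match taxon names")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate taxon names in alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_sites(self) -> int:
        """Alignment length in codons."""
        return self.matrix.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def codon_str(self, taxon: int | str, site: int) -> str | None:
        if isinstance(taxon, str):
            taxon = self.names.index(taxon)
        state = self.matrix[taxon, site]
        return None if state == MISSING else SENSE_CODONS[state]

    def sequence_str(self, name: str) -> str:
        """Nucleotide string for one taxon, missing codons as '---'."""
        return "".join(
            SENSE_CODONS[s] if s != MISSING else "---" for s in self.row(name)
        )

    def take_taxa(self, names: Sequence[str]) -> "CodonAlignment":
        idx = [self.names.index(n) for n in names]
        return CodonAlignment(tuple(names), self.matrix[idx].copy())

    def patterns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Distinct site columns, their multiplicities, and site->pattern map."""
        cols, inverse, counts = np.unique(
            self.matrix.T, axis=0, return_inverse=True, return_counts=True
        )
        return cols.T, counts.astype(float), inverse

    @classmethod
    def from_sequences(
        cls,
        names: Iterable[str],
        sequences: Iterable[str],
        *,
        allow_stops: bool = False,
    ) -> "CodonAlignment":
        names = tuple(names)
        seqs = [s.upper().replace("U", "T") for s in sequences]
        if not names:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError("ragged alignment: rows differ in length")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(
                f"alignment length {length} is not divisible by 3"
            )
        n_sites = length // 3
        matrix = np.full((len(names), n_sites), MISSING, dtype=np.int16)
        for i, (name, seq) in enumerate(zip(names, seqs)):
            for s in range(n_sites):
                codon = seq[3 * s : 3 * s + 3]
                if codon in CODON_INDEX:
                    matrix[i, s] = CODON_INDEX[codon]
                elif codon in STOP_CODONS:
                    if not allow_stops:
                        raise AlignmentError(
                            f"in-frame stop codon {codon} in taxon "
                            f"'{name}' at codon site {s + 1}"
                        )
                    # tolerated stop is treated as missing in likelihood space
                    matrix[i, s] = MISSING
                # anything else (gap, N, IUPAC ambiguity) stays MISSING
        if np.all(matrix == MISSING):
            raise AlignmentError("no observable codons (all-gap alignment)")
        return cls(names, matrix)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequence_str(n)), id=n, description="")
            for n in self.names
        ]
        SeqIO.write(records, str(path), "fasta")


def read_codon_fasta(
    path: str | Path,
    code: GeneticCode | None = None,
    *,
    allow_stops: bool = False,
) -> CodonAlignment:
    """Read an aligned, in-frame FASTA into a :class:`CodonAlignment`.

    In likelihood mode (``allow_stops=False``) an in-frame stop raises an
    :class:`AlignmentError` naming the offending taxon and codon site.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    return CodonAlignment.from_sequences(
        [r.id for r in records],
        [str(r.seq) for r in records],
        allow_stops=allow_stops,
    )


def read_nucleotide_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Raw aligned nucleotide rows (name, sequence), uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    rows = [(r.id, str(r.seq).upper()) for r in records]
    if len({len(s) for _, s in rows}) != 1:
        raise AlignmentError("ragged alignment: rows differ in length")
    return rows


def write_nucleotide_fasta(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in rows]
    SeqIO.write(records, str(path), "fasta")
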