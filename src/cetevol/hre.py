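"""Hypoxia-response-element (HRE) scanning in promoter alignments.

The consensus HRE is the pentamer ACGTG bound by Hypoxia-Inducible
Factor-1.  Hits found in individual (gap-stripped) promoter rows are mapped
back to alignment columns; hits whose column footprints overlap in at least
3 of 5 positions are grouped as homologous, and groups present in at least
``min_species`` species are called conserved.  A conserved group is
clade-specific when every species carrying it belongs to a single clade.
Forward strand only by default; HIF binding is functionally strand-agnostic,
so reverse-complement scanning is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

HRE_MOTIF = "ACGTG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class MotifError(ValueError):
    pass


@dataclass
class MotifHit:
    species: str
    start: int  # 1-based position in the species' ungapped sequence
    columns: tuple[int, ...]  # 0-based alignment columns of the motif bases
    strand: str = "+"
    group: int = -1
    conservation_set: frozenset[str] = frozenset()
    specificity: str = "none"  # all-species | clade:<name> | none
    # promoter rows are the upstream region ending at the CDS start, so the
    # distance upstream is negative and -13000 reads as "~13 kb upstream"
    upstream_bp: int = 0

    @property
    def upstream_kb(self) -> float:
        return round(self.upstream_bp / 1000.0, 2)


def _check_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif or any(b not in "ACGT" for b in motif):
        raise MotifError(f"motif '{motif}' contains non-ACGT characters")
    return motif


def find_motifs(sequence: str, motif: str = HRE_MOTIF) -> list[int]:
    """All (possibly overlapping) 1-based occurrence starts; gaps skipped."""
    motif = _check_motif(motif)
    seq = sequence.upper().replace("-", "")
    k = len(motif)
    return [i + 1 for i in range(len(seq) - k + 1) if seq[i : i + k] == motif]


def _row_hits(
    species: str, aligned: str, motif: str, strand: str
) -> list[MotifHit]:
    cols = [c for c, ch in enumerate(aligned) if ch != "-"]
    seq = "".join(aligned[c] for c in cols).upper()
    if strand == "-":
        target = motif.translate(_COMPLEMENT)[::-1]
    else:
        target = motif
    k = len(target)
    hits = []
    for i in range(len(seq) - k + 1):
        if seq[i : i + k] == target:
            hits.append(
                MotifHit(
                    species=species,
                    start=i + 1,
                    columns=tuple(cols[i : i + k]),
                    strand=strand,
                    upstream_bp=(i + 1) - (len(seq) + 1),
                )
            )
    return hits


def conserved_motifs(
    rows: Sequence[tuple[str, str]],
    min_species: int,
    motif: str = HRE_MOTIF,
    *,
    both_strands: bool = False,
) -> list[MotifHit]:
    """Conserved motif hits across an aligned promoter set.

    Hits sharing >= 3 alignment columns form one homologous group; groups
    observed in at least ``min_species`` distinct species are returned, each
    hit annotated with its group id and conservation set.
    """
    if min_species < 1:
        raise MotifError("min_species must be >= 1")
    motif = _check_motif(motif)
    hits: list[MotifHit] = []
    for species, aligned in rows:
        hits.extend(_row_hits(species, aligned, motif, "+"))
        if both_strands:
            hits.extend(_row_hits(species, aligned, motif, "-"))
    # union-find over hits by column-footprint overlap
    parent = list(range(len(hits)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    by_column: dict[int, list[int]] = {}
    for i, h in enumerate(hits):
        for c in h.columns:
            by_column.setdefault(c, []).append(i)
    for i, h in enumerate(hits):
        seen: dict[int, int] = {}
        for c in h.columns:
            for j in by_column[c]:
                if j > i:
                    seen[j] = seen.get(j, 0) + 1
        for j, overlap in seen.items():
            if overlap >= 3:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(hits)):
        groups.setdefault(find(i), []).append(i)
    kept: list[MotifHit] = []
    for gid, (root, members) in enumerate(sorted(groups.items())):
        species_set = frozenset(hits[i].species for i in members)
        if len(species_set) < min_species:
            continue
        for i in members:
            hits[i].group = gid
            hits[i].conservation_set = species_set
            kept.append(hits[i])
    return kept


def clade_specific_counts(
    hits: Sequence[MotifHit],
    clades: dict[str, Sequence[str]],
) -> dict[str, int]:
    """Per-clade counts of clade-specific conserved groups.

    Every species appearing in a conservation set must belong to exactly one
    clade.  Returns one count per clade plus ``"all-species"`` for groups
    conserved across every species in the partition.
    """
    species_to_clade: dict[str, str] = {}
    for clade, members in clades.items():
        for sp in members:
            if sp in species_to_clade:
                raise MotifError(f"species '{sp}' assigned to two clades")
            species_to_clade[sp] = clade
    all_species = frozenset(species_to_clade)
    counts = {clade: 0 for clade in clades}
    counts["all-species"] = 0
    seen_groups: set[int] = set()
    for hit in hits:
        if hit.group in seen_groups or hit.group < 0:
            continue
        seen_groups.add(hit.group)
        missing = hit.conservation_set - all_species
        if missing:
            raise MotifError(
                f"species missing from the clade partition: {sorted(missing)}"
            )
        member_clades = {species_to_clade[sp] for sp in hit.conservation_set}
        if hit.conservation_set == all_species:
            counts["all-species"] += 1
            specificity = "all-species"
        elif len(member_clades) == 1:
            (clade,) = member_clades
            counts[clade] += 1
            specificity = f"clade:{clade}"
        else:
            specificity = "none"
        for h in hits:
            if h.group == hit.group:
                h.specificity = specificity
    return counts
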