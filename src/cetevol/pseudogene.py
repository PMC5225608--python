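"""Gene-inactivating lesion detection in coding alignments.

The scanner is alignment-relative: one taxon with an intact open reading
frame serves as the reference, and every other row is compared to it.
Premature in-frame stops are nonsense events; gap runs whose length is not a
multiple of three shift the reading frame, and the first stop read in the
shifted frame is attached to the causative indel; an (essentially) fully
gapped exon is an exon-loss event.  Coordinates are 1-based codon positions
in the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genetics import STOP_CODONS

EXON_LOSS_FRACTION = 0.95
_AMBIGUOUS_FRACTION = 0.20


class PseudogeneError(ValueError):
    pass


@dataclass
class DisruptionEvent:
    """One gene-disrupting lesion in one taxon."""

    taxon: str
    kind: str  # nonsense | frameshift-insertion | frameshift-deletion | exon-loss
    position: int  # 1-based reference codon position
    exon: int | None = None  # 1-based exon index, when an exon map is given
    length: int | None = None  # indel length in nucleotides
    stop_codon: str | None = None
    induced_stop_position: int | None = None  # for frameshifts
    truncation_fraction: float | None = None  # for nonsense events
    ambiguous: bool = False
    description: str = ""

    def key(self) -> tuple[str, int]:
        return (self.kind, self.position)


def _reference_checks(ref_seq: str, ref_name: str) -> int:
    """Validate the reference ORF; returns its length in codons."""
    ungapped = ref_seq.replace("-", "")
    if len(ungapped) % 3 != 0:
        raise PseudogeneError(
            f"choose an intact reference: '{ref_name}' has length "
            f"{len(ungapped)} (not divisible by 3)"
        )
    n_codons = len(ungapped) // 3
    for c in range(n_codons - 1):
        codon = ungapped[3 * c : 3 * c + 3]
        if codon in STOP_CODONS:
            raise PseudogeneError(
                f"choose an intact reference: '{ref_name}' has a premature "
                f"stop {codon} at codon {c + 1}"
            )
    return n_codons


def scan_orf(
    rows: Sequence[tuple[str, str]],
    reference: str,
    exons: Sequence[tuple[int, int]] | None = None,
) -> list[DisruptionEvent]:
    """Scan every non-reference taxon for ORF-disrupting lesions.

    ``rows`` is an aligned nucleotide alignment as (name, sequence) pairs;
    ``exons`` optionally gives 0-based half-open nucleotide intervals in
    reference coordinates.  The reference's own terminal stop is exempt.
    """
    seqs = {n: s.upper() for n, s in rows}
    if reference not in seqs:
        raise PseudogeneError(f"reference taxon '{reference}' not in alignment")
    ref = seqs[reference]
    n_ref_codons = _reference_checks(ref, reference)
    ref_ungapped = ref.replace("-", "")
    terminal_is_stop = ref_ungapped[-3:] in STOP_CODONS
    last_coding_codon = n_ref_codons - 1 if terminal_is_stop else n_ref_codons

    # per alignment column: reference nucleotide index (0-based) or None
    ref_pos: list[int | None] = []
    k = 0
    for ch in ref:
        if ch == "-":
            ref_pos.append(None)
        else:
            ref_pos.append(k)
            k += 1

    def exon_of(nt: int) -> int | None:
        if exons is None:
            return None
        for i, (a, b) in enumerate(exons):
            if a <= nt < b:
                return i + 1
        return None

    events: list[DisruptionEvent] = []
    for name, seq in seqs.items():
        if name == reference:
            continue
        if len(seq) != len(ref):
            raise PseudogeneError("ragged alignment")

        # --- exon loss --------------------------------------------------
        lost_exons: set[int] = set()
        if exons is not None:
            for i, (a, b) in enumerate(exons):
                cols = [
                    c
                    for c, rp in enumerate(ref_pos)
                    if rp is not None and a <= rp < b
                ]
                if not cols:
                    continue
                gapped = sum(1 for c in cols if seq[c] == "-")
                frac = gapped / len(cols)
                if frac >= EXON_LOSS_FRACTION:
                    lost_exons.add(i + 1)
                    events.append(
                        DisruptionEvent(
                            taxon=name,
                            kind="exon-loss",
                            position=a // 3 + 1,
                            exon=i + 1,
                            description=f"{gapped}/{len(cols)} exon columns gapped",
                        )
                    )
                elif frac > _AMBIGUOUS_FRACTION:
                    events.append(
                        DisruptionEvent(
                            taxon=name,
                            kind="exon-loss",
                            position=a // 3 + 1,
                            exon=i + 1,
                            ambiguous=True,
                            description=(
                                f"partially gapped exon ({frac:.0%}); "
                                "alignment truncation vs deletion undecided"
                            ),
                        )
                    )

        def in_lost_exon(col: int) -> bool:
            rp = ref_pos[col]
            if rp is None:
                # insertion columns inherit the surrounding exon
                left = col - 1
                while left >= 0 and ref_pos[left] is None:
                    left -= 1
                rp = ref_pos[left] if left >= 0 else 0
            e = exon_of(rp)
            return e in lost_exons

        # --- indel runs --------------------------------------------------
        frameshifts: list[DisruptionEvent] = []
        run_kind = None  # "del" (ref base, taxon gap) / "ins" (ref gap, taxon base)
        run_len = 0
        run_start_nt = 0

        def close_run() -> None:
            nonlocal run_kind, run_len
            if run_kind is not None and run_len % 3 != 0:
                kind = (
                    "frameshift-deletion" if run_kind == "del" else "frameshift-insertion"
                )
                ev = DisruptionEvent(
                    taxon=name,
                    kind=kind,
                    position=run_start_nt // 3 + 1,
                    exon=exon_of(run_start_nt),
                    length=run_len,
                    description=f"{run_len} nt "
                    + ("deleted" if run_kind == "del" else "inserted"),
                )
                events.append(ev)
                frameshifts.append(ev)
            run_kind = None
            run_len = 0

        last_ref_nt = 0
        for col in range(len(ref)):
            if in_lost_exon(col):
                continue
            r, t = ref[col], seq[col]
            if ref_pos[col] is not None:
                last_ref_nt = ref_pos[col]
            if r != "-" and t == "-":
                if run_kind != "del":
                    close_run()
                    run_kind = "del"
                    run_start_nt = ref_pos[col]  # type: ignore[assignment]
                run_len += 1
            elif r == "-" and t != "-":
                if run_kind != "ins":
                    close_run()
                    run_kind = "ins"
                    run_start_nt = min(last_ref_nt + 1, n_ref_codons * 3 - 1)
                run_len += 1
            else:
                close_run()
        close_run()

        # --- stop scan in the taxon's own reading ------------------------
        # stream of (base, reference codon at that point, frame offset)
        stream: list[tuple[str, int, int]] = []
        t_count = 0
        r_count = 0
        for col in range(len(ref)):
            if in_lost_exon(col):
                continue
            r, t = ref[col], seq[col]
            if r != "-":
                r_count += 1
            if t != "-":
                ref_here = ref_pos[col] if ref_pos[col] is not None else max(r_count - 1, 0)
                stream.append((t, ref_here // 3 + 1, t_count - (r_count - 1)))
                t_count += 1

        open_shift: DisruptionEvent | None = None
        pending = sorted(frameshifts, key=lambda e: e.position)
        for i in range(0, len(stream) - 2, 3):
            b0, codon_pos, offset = stream[i]
            codon = b0 + stream[i + 1][0] + stream[i + 2][0]
            in_frame = offset % 3 == 0  # taxon reading frame == reference frame
            while pending and pending[0].position <= codon_pos:
                open_shift = pending.pop(0)
            if codon not in STOP_CODONS:
                continue
            if codon_pos > last_coding_codon:
                break  # reference's own terminal stop region
            if in_frame and open_shift is None:
                events.append(
                    DisruptionEvent(
                        taxon=name,
                        kind="nonsense",
                        position=codon_pos,
                        exon=exon_of((codon_pos - 1) * 3),
                        stop_codon=codon,
                        truncation_fraction=round(
                            (last_coding_codon - codon_pos) / last_coding_codon, 4
                        ),
                        description=f"premature stop {codon}",
                    )
                )
            elif open_shift is not None and open_shift.induced_stop_position is None:
                open_shift.induced_stop_position = codon_pos
                open_shift.stop_codon = codon
                open_shift.description += f"; induced stop {codon} at codon {codon_pos}"
                open_shift = None
    return events


@dataclass
class LineageSummary:
    """Per-gene x taxon event matrix plus clade inactivation calls."""

    matrix: dict[str, dict[str, list[str]]]  # gene -> taxon -> event kinds
    clade_status: list[dict]  # gene, clade, inactivated, annotation

    def inactivated_clades(self, gene: str) -> list[str]:
        return [
            r["clade"]
            for r in self.clade_status
            if r["gene"] == gene and r["inactivated"]
        ]


def lineage_disruption_summary(
    events_by_gene: dict[str, list[DisruptionEvent]],
    clades: dict[str, Sequence[str]],
) -> LineageSummary:
    """Summarize lesions per gene and flag fully disrupted clades.

    A clade is "inactivated" for a gene when every member carries at least
    one non-ambiguous disrupting event; the annotation is "shared" when a
    single (kind, position) lesion is present in every member (consistent
    with one origin) and "independent" otherwise.
    """
    matrix: dict[str, dict[str, list[str]]] = {}
    clade_rows: list[dict] = []
    for gene, events in events_by_gene.items():
        per_taxon: dict[str, list[DisruptionEvent]] = {}
        for ev in events:
            if ev.ambiguous:
                continue
            per_taxon.setdefault(ev.taxon, []).append(ev)
        matrix[gene] = {
            taxon: sorted({e.kind for e in evs}) for taxon, evs in per_taxon.items()
        }
        for clade, members in clades.items():
            hit = [t for t in members if per_taxon.get(t)]
            inactivated = len(hit) == len(members) and len(members) > 0
            annotation = ""
            if inactivated:
                shared = set.intersection(
                    *({e.key() for e in per_taxon[t]} for t in members)
                )
                annotation = "shared" if shared else "independent"
            clade_rows.append(
                {
                    "gene": gene,
                    "clade": clade,
                    "inactivated": inactivated,
                    "annotation": annotation,
                }
            )
    return LineageSummary(matrix, clade_rows)
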