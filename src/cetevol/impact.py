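"""Damaging vs neutral substitution-rate contrast between branch classes.

Impact predictions (PolyPhen-2, SIFT, PROVEAN) are external inputs ingested
as category labels and binarized per predictor; the contrast normalizes the
per-class replacement counts by the number of DNA substitutions at third
codon positions on the same branches (an approximately neutral yardstick).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alignment import MISSING, CodonAlignment
from .ancestral import AncestralStates, ReplacementEvent
from .genetics import SENSE_CODONS
from .phylo import Phylogeny

# binarization maps are total over each predictor's vocabulary (lowercased)
PREDICTOR_MAPS: dict[str, dict[str, str]] = {
    "polyphen-2": {
        "probably damaging": "damaging",
        "possibly damaging": "damaging",
        "benign": "neutral",
    },
    "sift": {"damaging": "damaging", "tolerated": "neutral"},
    "provean": {"deleterious": "damaging", "neutral": "neutral"},
}


class ImpactError(ValueError):
    pass


@dataclass(frozen=True)
class ImpactLabel:
    predictor: str
    category: str
    impact: str  # damaging | neutral


@dataclass
class RateContrast:
    """The per-branch-class damaging/neutral rate table for one predictor."""

    predictor: str
    focal_class: str
    rest_class: str
    focal_damaging: int
    focal_neutral: int
    focal_third_pos: int
    rest_damaging: int
    rest_neutral: int
    rest_third_pos: int

    @property
    def focal_damaging_rate(self) -> float:
        return self.focal_damaging / self.focal_third_pos

    @property
    def focal_neutral_rate(self) -> float:
        return self.focal_neutral / self.focal_third_pos

    @property
    def rest_damaging_rate(self) -> float:
        return self.rest_damaging / self.rest_third_pos

    @property
    def rest_neutral_rate(self) -> float:
        return self.rest_neutral / self.rest_third_pos

    @property
    def damaging_ratio(self) -> float:
        return self.focal_damaging_rate / self.rest_damaging_rate

    @property
    def neutral_ratio(self) -> float:
        return self.focal_neutral_rate / self.rest_neutral_rate

    @staticmethod
    def percent_greater(ratio: float) -> str:
        """Render a rate ratio as e.g. '162% greater' (2.619 -> 162)."""
        return f"{round((ratio - 1) * 100)}% greater"

    def as_record(self) -> dict:
        return {
            "predictor": self.predictor,
            "focal_damaging": self.focal_damaging,
            "focal_neutral": self.focal_neutral,
            "focal_damaging_rate": round(self.focal_damaging_rate, 3),
            "focal_neutral_rate": round(self.focal_neutral_rate, 3),
            "rest_damaging": self.rest_damaging,
            "rest_neutral": self.rest_neutral,
            "rest_damaging_rate": round(self.rest_damaging_rate, 3),
            "rest_neutral_rate": round(self.rest_neutral_rate, 3),
            "damaging_ratio": round(self.damaging_ratio, 3),
            "neutral_ratio": round(self.neutral_ratio, 3),
        }


def binarize_category(predictor: str, category: str) -> str:
    pmap = PREDICTOR_MAPS.get(predictor.lower())
    if pmap is None:
        raise ImpactError(f"unknown predictor '{predictor}'")
    impact = pmap.get(category.strip().lower())
    if impact is None:
        raise ImpactError(
            f"unknown category '{category}' for predictor '{predictor}'"
        )
    return impact


def classify_replacements(
    events: list[ReplacementEvent],
    labels: pd.DataFrame,
    predictor: str,
) -> pd.DataFrame:
    """Join replacement events with one predictor's impact labels.

    ``labels`` columns: gene, position, from, to, predictor, category.
    Every event must have a label row for the requested predictor.
    """
    sub = labels[labels["predictor"].str.lower() == predictor.lower()]
    keyed: dict[tuple, str] = {}
    for _, r in sub.iterrows():
        keyed[(r["gene"], int(r["position"]), r["from"], r["to"])] = r["category"]
    rows = []
    for ev in events:
        pos = ev.ref_position if ev.ref_position is not None else ev.position
        key = (ev.gene, pos, ev.ancestral, ev.derived)
        if key not in keyed:
            raise ImpactError(
                f"no {predictor} label for {ev.gene} {ev.ancestral}{pos}{ev.derived}"
            )
        category = keyed[key]
        rows.append(
            {
                "gene": ev.gene,
                "position": pos,
                "from": ev.ancestral,
                "to": ev.derived,
                "branch": ev.branch,
                "branch_class": ev.branch_class,
                "predictor": predictor,
                "category": category,
                "impact": binarize_category(predictor, category),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "position",
            "from",
            "to",
            "branch",
            "branch_class",
            "predictor",
            "category",
            "impact",
        ],
    )


def third_position_substitutions(
    alignment: CodonAlignment,
    tree: Phylogeny,
    states: AncestralStates,
) -> dict[str, int]:
    """Count per branch class the sites whose parent/child codons differ at
    the third nucleotide position."""
    counts: dict[str, int] = {}
    for edge in tree.edges():
        parent_seq = states.sequences[edge.parent.name]
        child_seq = (
            alignment.row(edge.name) if edge.is_leaf else states.sequences[edge.name]
        )
        label = tree.class_names.get(edge.cls, str(edge.cls))
        c = 0
        for a, d in zip(parent_seq, child_seq):
            if a == MISSING or d == MISSING:
                continue
            if SENSE_CODONS[a][2] != SENSE_CODONS[d][2]:
                c += 1
        counts[label] = counts.get(label, 0) + c
    return counts


def rate_contrast(
    labelled: pd.DataFrame,
    third_pos_counts: dict[str, int],
    focal_class: str,
    rest_class: str,
) -> RateContrast:
    """Damaging/neutral rates per branch class and their focal/rest ratios."""
    for cls in (focal_class, rest_class):
        if third_pos_counts.get(cls, 0) <= 0:
            raise ImpactError(
                f"zero third-position substitution count for class '{cls}'"
            )
    (predictor,) = labelled["predictor"].unique()

    def count(cls: str, impact: str) -> int:
        return int(
            (
                (labelled["branch_class"] == cls) & (labelled["impact"] == impact)
            ).sum()
        )

    return RateContrast(
        predictor=predictor,
        focal_class=focal_class,
        rest_class=rest_class,
        focal_damaging=count(focal_class, "damaging"),
        focal_neutral=count(focal_class, "neutral"),
        focal_third_pos=third_pos_counts[focal_class],
        rest_damaging=count(rest_class, "damaging"),
        rest_neutral=count(rest_class, "neutral"),
        rest_third_pos=third_pos_counts[rest_class],
    )


def rate_contrast_from_counts(
    predictor: str,
    focal: tuple[int, int, int],
    rest: tuple[int, int, int],
    focal_class: str = "ancestral whale",
    rest_class: str = "rest",
) -> RateContrast:
    """Contrast directly from (damaging, neutral, third-position) counts."""
    fd, fn, ft = focal
    rd, rn, rt = rest
    if ft <= 0 or rt <= 0:
        raise ImpactError("zero third-position substitution denominator")
    return RateContrast(
        predictor, focal_class, rest_class, fd, fn, ft, rd, rn, rt
    )
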