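import numpy as np
import pandas as pd
import pytest

from cetevol.alignment import CodonAlignment
from cetevol.ancestral import AncestralStates, ReplacementEvent
from cetevol.genetics import CODON_INDEX
from cetevol.impact import (
    ImpactError,
    RateContrast,
    binarize_category,
    classify_replacements,
    rate_contrast,
    rate_contrast_from_counts,
    third_position_substitutions,
)
from cetevol.phylo import parse_newick_labelled


@pytest.mark.parametrize(
    "predictor,category,expected",
    [
        ("PolyPhen-2", "Probably damaging", "damaging"),
        ("PolyPhen-2", "possibly damaging", "damaging"),
        ("PolyPhen-2", "benign", "neutral"),
        ("SIFT", "Damaging", "damaging"),
        ("SIFT", "Tolerated", "neutral"),
        ("PROVEAN", "Deleterious", "damaging"),
        ("PROVEAN", "Neutral", "neutral"),
    ],
)
def test_binarization_vocabulary(predictor, category, expected):
    assert binarize_category(predictor, category) == expected


def test_unknown_category_named_in_error():
    with pytest.raises(ImpactError, match="mystery"):
        binarize_category("SIFT", "mystery")
    with pytest.raises(ImpactError, match="NotAPredictor"):
        binarize_category("NotAPredictor", "benign")


def _event(pos, frm, to, cls):
    return ReplacementEvent(
        gene="FGF9", position=pos, ancestral=frm, derived=to,
        branch="b", branch_class=cls,
    )


def test_classify_joins_labels():
    events = [_event(203, "D", "G", "ancestral whale"), _event(17, "V", "A", "rest")]
    labels = pd.DataFrame(
        [
            {"gene": "FGF9", "position": 203, "from": "D", "to": "G",
             "predictor": "PolyPhen-2", "category": "Probably damaging"},
            {"gene": "FGF9", "position": 17, "from": "V", "to": "A",
             "predictor": "PolyPhen-2", "category": "benign"},
        ]
    )
    out = classify_replacements(events, labels, "PolyPhen-2")
    assert list(out["impact"]) == ["damaging", "neutral"]


def test_classify_requires_complete_labels():
    events = [_event(1, "A", "S", "rest")]
    labels = pd.DataFrame(
        [{"gene": "x", "position": 9, "from": "A", "to": "S",
          "predictor": "SIFT", "category": "Tolerated"}]
    )
    with pytest.raises(ImpactError, match="no SIFT label"):
        classify_replacements(events, labels, "SIFT")


class TestThirdPosition:
    def _setup(self, child_codons):
        tree = parse_newick_labelled("((A:0.1,B:0.1)u:0.1,C:0.1);")
        tree.mark_clade(["A", "B"], 1, include_stem=True, name="whales")
        root = tree.root.name
        parent = ["ATG", "CAT", "GGT"]
        aln = CodonAlignment.from_sequences(
            ["A", "B", "C"], ["".join(child_codons), "".join(parent), "".join(parent)]
        )
        seqs = {
            root: np.array([CODON_INDEX[c] for c in parent], dtype=np.int16),
            "u": np.array([CODON_INDEX[c] for c in parent], dtype=np.int16),
        }
        n = 3
        states = AncestralStates(
            (root, "u"),
            seqs,
            {k: np.ones(n) for k in seqs},
            {k: np.full((n, 61), 1 / 61) for k in seqs},
        )
        return aln, tree, states

    def test_identical_sequences_count_zero(self):
        aln, tree, states = self._setup(["ATG", "CAT", "GGT"])
        counts = third_position_substitutions(aln, tree, states)
        assert counts == {"whales": 0, "background": 0}

    def test_planted_third_position_changes_counted_in_class(self):
        # two third-position changes on the edge to leaf A (class whales)
        aln, tree, states = self._setup(["ATC", "CAC", "GGT"])
        counts = third_position_substitutions(aln, tree, states)
        assert counts["whales"] == 2 and counts["background"] == 0

    def test_first_position_change_not_counted(self):
        aln, tree, states = self._setup(["TTG", "CAT", "GGT"])
        counts = third_position_substitutions(aln, tree, states)
        assert counts == {"whales": 0, "background": 0}


class TestRateContrast:
    def test_published_style_rates(self):
        """3 damaging / 10 neutral over 39 third-position substitutions."""
        rc = rate_contrast_from_counts("PolyPhen-2", (3, 10, 39), (681, 5720, 23200))
        assert round(rc.focal_damaging_rate, 3) == 0.077
        assert round(rc.focal_neutral_rate, 3) == 0.256
        assert rc.damaging_ratio > 1

    def test_percent_greater_rendering(self):
        assert RateContrast.percent_greater(2.619) == "162% greater"

    def test_equal_rates_give_unit_ratios(self):
        rc = rate_contrast_from_counts("SIFT", (2, 4, 10), (20, 40, 100))
        assert rc.damaging_ratio == pytest.approx(1.0)
        assert rc.neutral_ratio == pytest.approx(1.0)

    def test_swap_inverts_ratios(self):
        rc = rate_contrast_from_counts("SIFT", (3, 10, 39), (681, 5720, 23200))
        sw = rate_contrast_from_counts("SIFT", (681, 5720, 23200), (3, 10, 39))
        assert sw.damaging_ratio == pytest.approx(1 / rc.damaging_ratio)
        assert sw.neutral_ratio == pytest.approx(1 / rc.neutral_ratio)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ImpactError):
            rate_contrast_from_counts("SIFT", (1, 1, 0), (1, 1, 10))

    def test_event_table_contrast(self):
        rows = []
        for i in range(3):
            rows.append(_event(i + 1, "D", "G", "ancestral whale"))
        for i in range(5):
            rows.append(_event(i + 10, "V", "A", "rest"))
        labels = pd.DataFrame(
            [
                {"gene": "FGF9", "position": e.position, "from": e.ancestral,
                 "to": e.derived, "predictor": "SIFT",
                 "category": "Damaging" if e.branch_class == "ancestral whale" else "Tolerated"}
                for e in rows
            ]
        )
        labelled = classify_replacements(rows, labels, "SIFT")
        rc = rate_contrast(labelled, {"ancestral whale": 30, "rest": 50}, "ancestral whale", "rest")
        assert rc.focal_damaging == 3 and rc.rest_neutral == 5
        assert rc.focal_damaging_rate == pytest.approx(0.1)

    def test_equal_planted_rates_give_median_ratio_near_one(self, rng):
        """200 resampled contrasts with identical true rates in both classes."""
        ratios = []
        for _ in range(200):
            fd = rng.binomial(40, 0.25)
            rd = rng.binomial(400, 0.25)
            if fd == 0 or rd == 0:
                continue
            rc = rate_contrast_from_counts("SIFT", (fd, 10, 40), (rd, 100, 400))
            ratios.append(rc.damaging_ratio)
        assert 0.8 <= float(np.median(ratios)) <= 1.25
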