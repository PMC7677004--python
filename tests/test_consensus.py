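"""Paired-read consensus rules and accuracy scoring."""

import pytest
from hypothesis import given, settings, strategies as st

from ampliscan.consensus import (
    AccuracySummary,
    ConsensusError,
    RankedAnnotation,
    annotation_depth,
    consensus_annotation,
    parse_annotation,
    score_against_truth,
)
from ampliscan.reference import Lineage, parse_lineage

LACTO = "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus"


class TestConsensusRules:
    def test_species_candidate_intersection(self):
        fwd = parse_annotation(f"{LACTO};crispatus/gasseri/jensenii")
        rev = parse_annotation(f"{LACTO};gasseri/jensenii/longum")
        result = consensus_annotation(fwd, rev)
        assert result.species_candidates == frozenset({"gasseri", "jensenii"})
        assert result.lineage.genus == "Lactobacillus"

    def test_family_agreement_genus_divergence_truncates_to_family(self):
        a = parse_annotation(f"{LACTO};iners")
        b = parse_annotation(
            "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Pediococcus"
        )
        result = consensus_annotation(a, b)
        assert result.lineage.family == "Lactobacillaceae"
        assert result.lineage.genus == ""
        assert result.lineage.depth == 5
        assert result.species_candidates is None

    def test_detail_asymmetry_keeps_more_detailed(self):
        genus_level = parse_annotation(LACTO)
        family_level = parse_annotation(
            "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae"
        )
        assert consensus_annotation(genus_level, family_level) == genus_level

    def test_disjoint_candidate_sets_fall_back_to_genus(self):
        a = parse_annotation(f"{LACTO};crispatus/gasseri")
        b = parse_annotation(f"{LACTO};jensenii/longum")
        result = consensus_annotation(a, b)
        assert result.lineage.genus == "Lactobacillus"
        assert result.lineage.species == ""
        assert result.species_candidates is None

    def test_singleton_intersection_becomes_species(self):
        a = parse_annotation(f"{LACTO};crispatus/gasseri")
        b = parse_annotation(f"{LACTO};crispatus/jensenii")
        result = consensus_annotation(a, b)
        assert result.lineage.species == "crispatus"
        assert result.species_candidates is None

    def test_one_sided_candidates_kept_under_compatible_lineage(self):
        a = parse_annotation(f"{LACTO};crispatus/gasseri")
        b = parse_annotation(LACTO)
        result = consensus_annotation(a, b)
        assert result.species_candidates == frozenset({"crispatus", "gasseri"})


LABELS = [
    ["Bacteria", "Archaea"],
    ["Firmicutes", "Actinobacteria"],
    ["Bacilli", "Clostridia"],
    ["Lactobacillales", "Bacillales"],
    ["Lactobacillaceae", "Listeriaceae"],
    ["Lactobacillus", "Pediococcus"],
    ["iners", "acidophilus"],
]


# pick a label variant per rank so genuine conflicts occur in generated pairs
rich_annotation = st.builds(
    lambda depth, picks, cands: _rich(depth, picks, cands),
    st.integers(min_value=0, max_value=7),
    st.tuples(*[st.integers(0, 1) for _ in range(7)]),
    st.sets(st.sampled_from(["crispatus", "gasseri", "jensenii", "longum"]), max_size=3),
)


def _rich(depth, picks, cands):
    ranks = tuple(LABELS[i][picks[i]] for i in range(depth)) + ("",) * (7 - depth)
    if depth == 6 and len(cands) >= 2:
        return RankedAnnotation(Lineage(ranks), frozenset(cands))
    return RankedAnnotation(Lineage(ranks))


class TestConsensusProperties:
    @given(rich_annotation, rich_annotation)
    @settings(derandomize=True, max_examples=300)
    def test_commutative(self, a, b):
        assert consensus_annotation(a, b) == consensus_annotation(b, a)

    @given(rich_annotation)
    @settings(derandomize=True, max_examples=200)
    def test_idempotent(self, a):
        assert consensus_annotation(a, a) == a

    @given(rich_annotation, rich_annotation)
    @settings(derandomize=True, max_examples=300)
    def test_depth_bounded_by_max(self, a, b):
        c = consensus_annotation(a, b)
        assert annotation_depth(c) <= max(annotation_depth(a), annotation_depth(b))

    @given(rich_annotation, rich_annotation)
    @settings(derandomize=True, max_examples=300)
    def test_prefix_absorption(self, a, b):
        # if a's filled ranks are a prefix of b's (and a has no species info
        # beyond it), the consensus is b
        if a.species_candidates is None and all(
            (not x) or x == y for x, y in zip(a.lineage.ranks, b.lineage.ranks)
        ) and a.depth <= b.depth:
            assert consensus_annotation(a, b) == b


class TestAnnotationDepth:
    def test_full_lineage_depth_seven(self, full_lineage):
        assert annotation_depth(RankedAnnotation(full_lineage)) == 7

    def test_empty_lineage_depth_zero(self):
        assert annotation_depth(parse_annotation("")) == 0

    def test_two_candidates_count_as_genus_depth(self):
        a = parse_annotation(f"{LACTO};crispatus/gasseri")
        assert annotation_depth(a) == 6

    def test_singleton_candidate_set_is_species_depth(self):
        a = RankedAnnotation(
            parse_annotation(LACTO).lineage, frozenset({"crispatus"})
        )
        assert annotation_depth(a) == 7
        assert a.lineage.species == "crispatus"


class TestScoring:
    def test_exact_match_all_correct(self, full_lineage):
        verdicts = score_against_truth(RankedAnnotation(full_lineage), full_lineage)
        assert verdicts == ("correct",) * 7

    def test_genus_level_annotation_leaves_species_unannotated(self, full_lineage):
        pred = parse_annotation(LACTO)
        verdicts = score_against_truth(pred, full_lineage)
        assert verdicts[:6] == ("correct",) * 6
        assert verdicts[6] == "unannotated"

    def test_candidate_set_containing_truth_is_ambiguous(self, full_lineage):
        pred = parse_annotation(f"{LACTO};crispatus/gasseri")
        assert score_against_truth(pred, full_lineage)[6] == "ambiguous"

    def test_candidate_set_excluding_truth_is_incorrect(self, full_lineage):
        pred = parse_annotation(f"{LACTO};gasseri/jensenii")
        assert score_against_truth(pred, full_lineage)[6] == "incorrect"

    def test_partial_truth_rejected(self):
        with pytest.raises(ConsensusError, match="fully specified"):
            score_against_truth(parse_annotation(LACTO), parse_lineage("Bacteria"))

    def test_planted_error_rate_recovered(self, full_lineage):
        # 20 predictions: 14 fully correct, 6 wrong at genus
        wrong = parse_annotation(
            "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Pediococcus"
        )
        right = RankedAnnotation(full_lineage)
        pairs = [(right, full_lineage)] * 14 + [(wrong, full_lineage)] * 6
        summary = AccuracySummary.from_pairs(pairs)
        assert summary.n_items == 20
        assert summary.per_rank["genus"]["incorrect"] == 6
        assert summary.per_rank["genus"]["correct"] == 14
        assert summary.per_rank["family"]["correct"] == 20
        # verdict counts partition the items at every rank
        for rank, counts in summary.per_rank.items():
            assert sum(counts.values()) == 20
        assert summary.deepest_correct[7] == 14
        assert summary.deepest_correct[5] == 6
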