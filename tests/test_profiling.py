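"""Frequency weights, consensus labels, distributions, contrasts, grid size."""

import pytest

from embedlex import (
    Annotation,
    RankedCandidate,
    SemanticType,
    annotation_grid_size,
    consensus_label,
    frequency_weights,
    mean_type_count,
    modifier_contrast,
    semantic_type_distribution,
)
from embedlex.profiling import SemanticDistribution
from embedlex.semantics import LABEL_ORDER


def cand(term, source, query="fever", cos=0.8, rank=1):
    return RankedCandidate(query=query, returned=term, cosine=cos, rank=rank, source_name=source)


def seven_source_lists(term_in: int):
    """One term present in ``term_in`` of 7 sources, plus per-source noise."""
    lists = {}
    for i in range(7):
        cands = [cand(f"noise{i}", f"s{i}")]
        if i < term_in:
            cands.append(cand("pyrexia", f"s{i}", rank=2))
        lists[f"s{i}"] = cands
    return lists


class TestFrequencyWeights:
    def test_single_source_term_scores_one_seventh(self):
        weights = {w.term: w for w in frequency_weights(seven_source_lists(1))}
        assert round(weights["pyrexia"].weight, 2) == 0.14
        assert weights["pyrexia"].source_count == 1

    def test_all_source_term_scores_one(self):
        weights = {w.term: w for w in frequency_weights(seven_source_lists(7))}
        assert weights["pyrexia"].weight == 1.0

    def test_three_of_seven(self):
        weights = {w.term: w for w in frequency_weights(seven_source_lists(3))}
        assert weights["pyrexia"].weight == pytest.approx(0.42857, abs=5e-6)

    def test_delimiter_variants_pool_into_one_record(self):
        lists = {
            "s1": [cand("dry_cough", "s1")],
            "s2": [cand("dry-cough", "s2")],
            "s3": [cand("Dry Cough", "s3")],
        }
        (w,) = frequency_weights(lists)
        assert w.source_count == 3 and w.weight == 1.0

    def test_single_source_run_all_weights_exactly_one(self):
        lists = {"only": [cand("a", "only"), cand("b", "only", rank=2)]}
        assert all(w.weight == 1.0 for w in frequency_weights(lists))

    def test_empty_source_mapping_rejected(self):
        with pytest.raises(ValueError, match="at least one source"):
            frequency_weights({})


class TestConsensusLabel:
    def test_majority_wins(self):
        out = consensus_label(
            [SemanticType.SYNONYM, SemanticType.SYNONYM, SemanticType.HYPERNYM]
        )
        assert out.label is SemanticType.SYNONYM and not out.tie_broken

    def test_three_way_tie_resolved_by_priority_and_flagged(self):
        out = consensus_label(
            [SemanticType.SYNONYM, SemanticType.HYPERNYM, SemanticType.OTHER]
        )
        assert out.label is SemanticType.SYNONYM and out.tie_broken

    def test_tie_without_synonym_uses_priority_order(self):
        out = consensus_label([SemanticType.QUALIFIER, SemanticType.HYPONYM])
        assert out.label is SemanticType.HYPONYM and out.tie_broken

    def test_single_annotator_label_stands(self):
        out = consensus_label([SemanticType.THERAPEUTIC])
        assert out.label is SemanticType.THERAPEUTIC and not out.tie_broken

    def test_no_labels_rejected(self):
        with pytest.raises(ValueError):
            consensus_label([])


def annotated_lists(label_plan):
    """Build top-k lists and matching unanimous annotations.

    label_plan: {source: {query: [labels in rank order]}}
    """
    nested, annotations = {}, []
    for source, queries in label_plan.items():
        nested[source] = {}
        for query, labels in queries.items():
            cands = [
                cand(f"{query}_t{i}", source, query=query, rank=i + 1)
                for i in range(len(labels))
            ]
            nested[source][query] = cands
            for c, lab in zip(cands, labels):
                for annotator in ("a1", "a2"):
                    annotations.append(
                        Annotation(
                            query=query,
                            returned=c.returned,
                            source_name=source,
                            annotator_id=annotator,
                            label=lab,
                        )
                    )
    return annotations, nested


class TestSemanticDistribution:
    def test_counts_match_planted_label_mix_exactly(self):
        plan = {
            "s1": {"fever": [SemanticType.SYNONYM] * 3 + [SemanticType.OTHER] * 2}
        }
        annotations, nested = annotated_lists(plan)
        (dist,) = semantic_type_distribution(annotations, nested)
        assert dist.counts[SemanticType.SYNONYM] == 3
        assert dist.counts[SemanticType.OTHER] == 2
        assert dist.total == 5

    def test_counts_conserved_per_source_query(self):
        plan = {
            "s1": {"fever": [SemanticType.SYNONYM] * 4, "cough": [SemanticType.HYPERNYM] * 4},
            "s2": {"fever": [SemanticType.NEGATION] * 4},
        }
        annotations, nested = annotated_lists(plan)
        for dist in semantic_type_distribution(annotations, nested):
            assert dist.total == 4

    def test_unlabeled_candidate_is_an_error(self):
        plan = {"s1": {"fever": [SemanticType.SYNONYM]}}
        annotations, nested = annotated_lists(plan)
        nested["s1"]["fever"].append(cand("fever_extra", "s1", rank=9))
        with pytest.raises(ValueError, match="fever_extra"):
            semantic_type_distribution(annotations, nested)


def dist(source, query, **counts):
    d = SemanticDistribution(source_name=source, query=query)
    for name, c in counts.items():
        d.counts[SemanticType(name)] = c
    return d


class TestMeanTypeCount:
    def test_single_cell(self):
        d = dist("s1", "fever", synonym=5)
        assert mean_type_count([d], {"s1"}, SemanticType.SYNONYM) == 5.0

    def test_mean_over_two_sources(self):
        ds = [dist("s1", "fever", synonym=6), dist("s2", "fever", synonym=8)]
        assert mean_type_count(ds, {"s1", "s2"}, SemanticType.SYNONYM) == 7.0

    def test_character_unit_group_mean_of_7_2(self):
        # 5 queries x 2 character-unit sources with synonym counts chosen
        # to average 7.2 (hand sum: 72 over 10 cells)
        counts = [9, 8, 7, 6, 6, 8, 7, 7, 7, 7]
        ds = [
            dist(f"char{i % 2}", f"q{i // 2}", synonym=c) for i, c in enumerate(counts)
        ]
        ds.append(dist("token1", "q0", synonym=2))  # outside the group
        assert mean_type_count(ds, {"char0", "char1"}, SemanticType.SYNONYM) == 7.2

    def test_order_invariance(self):
        ds = [dist("s1", "a", synonym=1), dist("s2", "b", synonym=4), dist("s1", "b", synonym=1)]
        forward = mean_type_count(ds, {"s1", "s2"}, SemanticType.SYNONYM)
        assert mean_type_count(ds[::-1], {"s2", "s1"}, SemanticType.SYNONYM) == forward

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mean_type_count([dist("s1", "a")], set(), SemanticType.SYNONYM)


class TestModifierContrast:
    def test_identical_distributions_give_zero_differences(self):
        ds = [dist("s1", "cough", qualifier=2), dist("s1", "dry cough", qualifier=2)]
        out = modifier_contrast(ds, {"cough": ("dry cough",)})
        assert all(c.difference == 0.0 for c in out)

    def test_constructed_qualifier_contrast(self):
        ds = [
            dist("s1", "dry cough", qualifier=4),
            dist("s2", "dry cough", qualifier=4),
            dist("s1", "cough", qualifier=1),
            dist("s2", "cough", qualifier=1),
        ]
        out = {
            (c.unmodified, c.modified, c.semantic_type): c
        for c in modifier_contrast(ds, {"cough": ("dry cough",)})}
        c = out[("cough", "dry cough", SemanticType.QUALIFIER)]
        assert (c.mean_modified, c.mean_unmodified, c.difference) == (4.0, 1.0, 3.0)

    def test_only_admitted_pairs_reported(self):
        ds = [
            dist("s1", "cough", qualifier=1),
            dist("s1", "dry cough", qualifier=2),
            dist("s1", "banana", qualifier=9),
        ]
        out = modifier_contrast(ds)  # packaged pair map
        assert {c.unmodified for c in out} == {"cough"}
        assert {c.modified for c in out} == {"dry cough"}

    def test_missing_variant_named_in_error(self):
        ds = [dist("s1", "cough", qualifier=1)]
        with pytest.raises(ValueError, match="dry cough"):
            modifier_contrast(ds, {"cough": ("dry cough",)})


class TestGridSize:
    def test_paper_scale_counts(self):
        assert annotation_grid_size(15 + 5 + 4, 7, 20, 3) == 10080

    def test_unit_grid(self):
        assert annotation_grid_size(1, 1, 1, 1) == 1

    def test_twenty_five_terms_give_10500(self):
        assert annotation_grid_size(25, 7, 20, 3) == 10500

    def test_accepts_collections(self):
        assert annotation_grid_size(["a", "b"], ["s1"], 3, ["a1", "a2"]) == 12

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            annotation_grid_size(0, 7, 20, 3)


def test_label_set_closed_with_ten_members_and_colors():
    assert len(LABEL_ORDER) == 10
    assert {lab.color for lab in LABEL_ORDER} == {
        "black", "green", "yellow", "blue", "light red",
        "dark red", "teal", "orange", "purple", "grey",
    }
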