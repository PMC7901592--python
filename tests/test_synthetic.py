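"""Planted-structure generators: embedding spaces, annotations, note corpora."""

import numpy as np
import pytest

from embedlex import (
    SemanticType,
    SynthAnnotationConfig,
    SynthCohortConfig,
    SynthEmbeddingConfig,
    build_expanded_lexicon,
    cohen_kappa,
    cosine,
    feature_proportions,
    generate_annotation_set,
    generate_cohort_notes,
    generate_embedding_space,
    match_features,
    top_k_neighbors,
)
from embedlex.semantics import LABEL_ORDER
from embedlex.synthetic import uniform_offdiagonal_kernel, write_truth

from helpers import brute_force_top, closed_form_expected_kappa, kappa_monte_carlo_se


class TestEmbeddingSpace:
    def test_empty_planting_yields_seeds_only(self):
        cfg = SynthEmbeddingConfig(
            seed_terms=("fever", "cough"),
            synonyms_per_seed=0,
            related_per_seed=0,
            distractor_count=0,
        )
        source, truth = generate_embedding_space(cfg)
        assert source.vocabulary == ["fever", "cough"]
        assert set(truth.role.values()) == {"seed"}

    def test_zero_jitter_forces_exact_cosine(self):
        cfg = SynthEmbeddingConfig(
            seed_terms=("fever",),
            synonyms_per_seed=1,
            related_per_seed=0,
            distractor_count=0,
            target_cos_synonym=0.95,
            cos_jitter=0.0,
        )
        source, _ = generate_embedding_space(cfg)
        assert cosine(source.vector("fever"), source.vector("fever_syn1")) == pytest.approx(
            0.95, abs=1e-9
        )

    def test_realized_cosines_stay_within_jitter(self):
        cfg = SynthEmbeddingConfig(
            seed_terms=("fever",), synonyms_per_seed=10, related_per_seed=10,
            distractor_count=0, cos_jitter=0.05, rng_seed=3,
        )
        source, truth = generate_embedding_space(cfg)
        for term, role in truth.role.items():
            if role in ("synonym", "related"):
                target = 0.9 if role == "synonym" else 0.4
                c = cosine(source.vector("fever"), source.vector(term))
                assert abs(c - target) <= 0.05 + 1e-9
                assert c == pytest.approx(truth.intended_cos[term], abs=1e-9)

    def test_top5_neighbors_are_the_planted_synonyms(self):
        cfg = SynthEmbeddingConfig(
            seed_terms=("fever",), dimension=50, synonyms_per_seed=5,
            related_per_seed=5, distractor_count=50, rng_seed=11,
        )
        source, truth = generate_embedding_space(cfg)
        expected = brute_force_top(source, "fever", 5)
        got = [c.returned for c in top_k_neighbors(source, "fever", k=5)]
        assert got == expected
        assert set(got) == truth.synonyms_of("fever")

    def test_distractors_near_orthogonal_to_every_seed(self):
        cfg = SynthEmbeddingConfig(
            seed_terms=("fever", "cough", "hypoxia"), distractor_count=30, rng_seed=5
        )
        source, truth = generate_embedding_space(cfg)
        for term, role in truth.role.items():
            if role == "distractor":
                for seed in ("fever", "cough", "hypoxia"):
                    assert abs(cosine(source.vector(seed), source.vector(term))) <= 0.3

    def test_identical_seed_bit_identical_output(self):
        cfg = SynthEmbeddingConfig(seed_terms=("fever", "dry cough"), rng_seed=42)
        s1, t1 = generate_embedding_space(cfg)
        s2, t2 = generate_embedding_space(cfg)
        assert s1.vocabulary == s2.vocabulary
        assert np.array_equal(s1.vectors, s2.vectors)
        assert t1.role == t2.role and t1.intended_cos == t2.intended_cos

    def test_dimension_below_two_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            SynthEmbeddingConfig(seed_terms=("fever",), dimension=1)

    def test_duplicate_seed_after_normalization_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SynthEmbeddingConfig(seed_terms=("dry cough", "dry_cough"))

    def test_synonym_target_must_exceed_related(self):
        with pytest.raises(ValueError, match="exceed"):
            SynthEmbeddingConfig(
                seed_terms=("fever",), target_cos_synonym=0.4, target_cos_related=0.5
            )

    def test_truth_table_export(self, tmp_path):
        cfg = SynthEmbeddingConfig(
            seed_terms=("fever",), synonyms_per_seed=1, related_per_seed=0,
            distractor_count=1,
        )
        _, truth = generate_embedding_space(cfg)
        path = write_truth(truth, tmp_path / "truth.tsv")
        lines = path.read_text().splitlines()
        assert lines[0] == "term\trole\tseed\tintended_cos"
        assert len(lines) == 4


class TestAnnotationSet:
    def test_perfect_agreement_gives_kappa_one(self):
        cfg = SynthAnnotationConfig(item_count=50, agreement_prob=1.0, rng_seed=1)
        annotations = generate_annotation_set(cfg)
        by = {}
        for a in annotations:
            by.setdefault(a.annotator_id, {})[a.item] = a.label
        keys = sorted(by["a1"])
        assert cohen_kappa(
            [by["a1"][k] for k in keys], [by["a2"][k] for k in keys]
        ) == 1.0

    def test_forced_disagreement_with_reference(self):
        cfg = SynthAnnotationConfig(item_count=200, agreement_prob=0.0, rng_seed=2)
        annotations, truth = generate_annotation_set(cfg, return_truth=True)
        # off-diagonal kernel never returns the reference label
        assert all(a.label is not truth[a.item] for a in annotations)

    def test_empirical_kappa_matches_closed_form(self):
        cfg = SynthAnnotationConfig(item_count=5000, agreement_prob=0.8, rng_seed=3)
        annotations = generate_annotation_set(cfg)
        by = {}
        for a in annotations:
            by.setdefault(a.annotator_id, {})[a.item] = a.label
        keys = sorted(by["a1"])
        observed = cohen_kappa([by["a1"][k] for k in keys], [by["a2"][k] for k in keys])
        base = np.full(len(LABEL_ORDER), 1 / len(LABEL_ORDER))
        kernel = uniform_offdiagonal_kernel()
        expected = closed_form_expected_kappa(base, kernel, 0.8)
        se = kappa_monte_carlo_se(base, kernel, 0.8, 5000)
        assert abs(observed - expected) <= 3 * se

    def test_deterministic_under_seed(self):
        cfg = SynthAnnotationConfig(item_count=100, rng_seed=9)
        a1 = generate_annotation_set(cfg)
        a2 = generate_annotation_set(cfg)
        assert a1 == a2

    def test_fewer_than_two_annotators_rejected(self):
        with pytest.raises(ValueError, match="2 annotators"):
            SynthAnnotationConfig(item_count=10, annotator_ids=("solo",))

    def test_non_stochastic_kernel_rejected(self):
        bad = np.eye(len(LABEL_ORDER)) * 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            SynthAnnotationConfig(item_count=10, confusion_kernel=bad)


def simple_lexicon():
    return build_expanded_lexicon({"fever": {"fever"}, "cough": {"cough"}})


class TestCohortNotes:
    def config(self, prevalence, n=50, seed=0):
        return SynthCohortConfig(
            cohorts=(("A", n),),
            concept_prevalence={"A": prevalence},
            rng_seed=seed,
        )

    def test_zero_prevalence_plants_nothing(self):
        lex = simple_lexicon()
        notes = generate_cohort_notes(self.config({"fever": 0.0, "cough": 0.0}), lex)
        table = match_features(notes, lex)
        assert not table[["fever", "cough"]].to_numpy().any()

    def test_full_prevalence_recovered_exactly(self):
        lex = simple_lexicon()
        notes = generate_cohort_notes(self.config({"fever": 1.0}), lex)
        props = {p.concept: p.proportion for p in feature_proportions(match_features(notes, lex))}
        assert props["fever"] == 1.0

    def test_partial_prevalence_within_binomial_bound(self):
        lex = simple_lexicon()
        notes = generate_cohort_notes(self.config({"fever": 0.4}, n=1000, seed=4), lex)
        props = {p.concept: p.proportion for p in feature_proportions(match_features(notes, lex))}
        assert abs(props["fever"] - 0.4) <= 3 * np.sqrt(0.4 * 0.6 / 1000)

    def test_filler_overlap_with_lexicon_rejected(self):
        lex = simple_lexicon()
        cfg = SynthCohortConfig(
            cohorts=(("A", 5),),
            concept_prevalence={"A": {"fever": 0.5}},
            filler_vocabulary=("stable", "fever"),
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_cohort_notes(cfg, lex)

    def test_notes_are_lowercase_alphanumeric_and_deterministic(self):
        lex = simple_lexicon()
        cfg = self.config({"fever": 0.5}, n=20, seed=8)
        n1 = generate_cohort_notes(cfg, lex)
        n2 = generate_cohort_notes(cfg, lex)
        assert n1 == n2
        for note in n1:
            assert note.note_text == note.note_text.lower()
            assert all(w.isalnum() for w in note.note_text.split())
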