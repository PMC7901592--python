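"""Expand a concept lexicon from synonym annotations and apply it to notes.

Builds a lexicon for "fever" and "cough" from consensus synonym labels,
plants those terms into synthetic discharge notes for two cohorts at
different prevalences, and reports the per-cohort proportion of patients
with each feature documented. Recovered proportions track the planted
prevalences up to binomial sampling error.
"""

from embedlex import (
    Annotation,
    SemanticType,
    SynthCohortConfig,
    build_expanded_lexicon,
    feature_proportions,
    generate_cohort_notes,
    match_features,
)

annotations = [
    Annotation(query="fever", returned=term, source_name=src,
               annotator_id=a, label=SemanticType.SYNONYM)
    for term in ("pyrexia", "fevers", "febrile")
    for src in ("source1", "source2")
    for a in ("a1", "a2", "a3")
]
lexicon = build_expanded_lexicon({"fever": {"fever"}, "cough": {"cough"}}, annotations)
print("fever lexicon:", sorted(lexicon.terms("fever")))

config = SynthCohortConfig(
    cohorts=(("pneumonia", 500), ("covid19", 500)),
    concept_prevalence={
        "pneumonia": {"fever": 0.61, "cough": 0.41},
        "covid19": {"fever": 0.84, "cough": 0.55},
    },
    rng_seed=3,
)
notes = generate_cohort_notes(config, lexicon)
table = match_features(notes, lexicon)
print(f"\n{len(notes)} notes for {len(table)} patients\n")
print("cohort      concept  documented")
for p in feature_proportions(table):
    print(f"{p.cohort:<11s} {p.concept:<8s} {p.numerator}/{p.denominator} = {p.rounded:.2f}")
print("\neach proportion counts patients with >=1 lexicon term in >=1 note")
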