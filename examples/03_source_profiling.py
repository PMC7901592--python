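"""Profile how returned terms recur across seven embedding sources.

Generates seven independent sources sharing the same planted synonym
vocabulary, queries each for "fever", and scores every returned term by
the fraction of sources that retrieved it (the word-cloud weight, bounded
between 1/7 = 0.14 and 1.0) plus its per-source cosine with the -1
sentinel marking sources that did not retrieve it.
"""

from embedlex import (
    SynthEmbeddingConfig,
    cross_source_cosines,
    frequency_weights,
    generate_embedding_space,
    top_k_neighbors,
)

lists = {}
for i in range(7):
    config = SynthEmbeddingConfig(
        seed_terms=("fever", "cough"),
        synonyms_per_seed=4,
        related_per_seed=4,
        distractor_count=30,
        rng_seed=100 + i,
        name=f"source{i + 1}",
    )
    source, _ = generate_embedding_space(config)
    lists[source.name] = top_k_neighbors(source, "fever", k=20)

weights = frequency_weights(lists)
print("term                      sources  weight")
for w in weights[:6] + weights[-2:]:
    print(f"{w.term:<26s} {w.source_count}/7     {w.weight:.2f}")

record = cross_source_cosines(weights[-1].term, lists)
present = {s: v for s, v in record.values.items() if v != -1.0}
print(f"\n'{record.term}' cosines: {present}; all other sources -1 (absent)")
print("weight 1.0 = retrieved by every source; 0.14 = by exactly one")
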