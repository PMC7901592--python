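# Methods

## Retrieval model

Each embedding source is a fixed lookup table from vocabulary keys to
real vectors; no subword inference is performed for out-of-vocabulary
terms, even for sources trained on character n-grams. Similarity is
cosine, computed in double precision with per-source vector norms cached
after the first query; results are clipped to [−1, 1] to absorb
floating-point overshoot. Rankings are therefore invariant to positive
rescaling of the vectors.

Queries are normalized per source before probing: case-folded if the
source was built lowercase, and multi-word phrases probed
underscore-joined first, then hyphen-joined, then verbatim — underscore
being the dominant phrase-key convention in public releases; the source
registry allows a per-source override since release documentation rarely
states the delimiter. All probed forms of the query are excluded from its
own ranking, so a case or delimiter variant of the query can never be
returned as its own neighbor. Ties in cosine break lexicographically on
the returned key, making every ranking deterministic.

Multi-word queries against unigram-only sources use the
`key_then_average` strategy by default: when no whole-phrase key exists,
the query vector is the unweighted mean of the constituent token vectors.
This is an explicit, configurable mechanism (`key_only` disables the
fallback); runs record the strategy used. The top-*k* depth defaults to
20. No filter removes morphological variants of the query from the
results: lexical variants ("fevers" for "fever") are legitimate lexicon
candidates, and character-unit sources return many of them.

## Agreement statistics

Pairwise Cohen kappa is computed over the full closed ten-label set even
when a stratum observes fewer labels, because the annotation instrument
fixes the label space regardless of what a particular query elicits. The
degenerate case p_e = 1 (both marginals concentrated on one identical
label) returns 1.0 when observed agreement is perfect and 0.0 otherwise,
keeping single-label strata reportable. Items are aligned across
annotators by the (query, returned term, source) key; an item labeled by
only one annotator of a pair is an error rather than a silent drop, and
duplicate (item, annotator) rows are rejected rather than last-wins,
since silent overwrites hide data errors. Category strata come from the
seed-list assignment (symptom / finding / disorder), never inferred from
the labels themselves. Only pairwise Cohen kappa is offered — no Fleiss
or weighted variants.

## Consensus labels and profiling

Reconciling multiple annotators into the single label used for
distributions and lexicon inclusion uses majority vote with a fixed,
documented tie-break priority (synonym > negation > hypernym > hyponym >
symptom/sign > disease/disorder > qualifier > anatomical location >
therapeutic > other); tie-broken items are flagged and counted in the
exports. The priority order front-loads the classes that matter most for
lexicon construction (synonyms) and for exclusion lists (negations), so
a tie never silently discards a potential lexicon term.

Cross-source term identity — for frequency weights and the per-source
cosine comparison — is case-folded, delimiter-normalized string equality
(underscore = hyphen = space), because the same concept surfaces as
"dry_cough", "dry-cough" or "dry cough" depending on the corpus. A term's
frequency weight is (number of sources whose top-*k* list contains it at
any rank) / (number of sources); with seven sources the weight lies
between 1/7 ≈ 0.14 and 1.0. In the cosine comparison, a source that did
not retrieve the term contributes the sentinel −1, which is unambiguous
because retrieved cosines of interest are non-negative in practice. The
weight table is the word-cloud computation; rendering is cosmetic and
out of the tested surface. Mean semantic-type counts are reported to two
decimal places.

The annotation-grid helper multiplies k × queries × sources × annotators
and takes its counts as inputs; it deliberately does not hard-code any
particular study's term count.

## Lexicon construction and matching

A concept's expanded term set is its seed term(s) plus every returned
term whose consensus label is synonym, pooled across sources, with
contributing sources recorded as provenance. Inclusion by consensus is
the default; an `include_rule="any"` variant admits terms any single
annotator called a synonym, since reasonable instruments differ here.
Terms are stored case-folded and delimiter-normalized.

Note matching is case-insensitive, word-boundary-delimited, contiguous
phrase containment; tokens of a multi-word term may be separated by a
single space, hyphen or underscore. Word boundaries are defined against
alphanumeric neighbors, so "cough" does not match inside "coughing" but
does match "cough," and "dry-cough". There is no stemming and no
negation/severity/temporality handling: the measured quantity is
*documentation* of a feature, not its asserted presence —
contextualization is a deliberate non-goal of the matching layer.
Aggregation is patient-level: any note counts, so the proportion for a
(cohort, concept) cell is (patients with ≥1 match) / (cohort size),
reported to 2 dp with the exact fraction alongside.

Severity roll-up encodes each group as required features plus an
any-of set: mild = any of {fever, cough, sore throat, malaise, headache,
muscle pain, nasal congestion}; moderate = cough AND shortness of
breath; severe = fever AND any of {dyspnea, respiratory distress,
tachypnea, hypoxia}. The severe rule is one explicit reading of a prose
description that links fever with severe respiratory features; the map
is plain data and overridable. A patient may satisfy several groups and
all satisfied groups are flagged.

## Synthetic data: what it emulates and what it does not

The embedding generator plants, around each seed direction, synonym
vectors at a target cosine (default 0.9), related-term vectors at a lower
target (default 0.4), and distractors near-orthogonal to every seed
(|cos| ≤ 0.3 by check-and-resample, capped at 1000 attempts). Angles are
forced exactly by construction: v = cos θ·u + sin θ·r with r a unit
vector obtained by Gram–Schmidt orthogonalization of a standard-normal
draw against the seed, and the realized cosine drawn uniformly within
the jitter band (default ±0.05) around the target. Seed directions
themselves are resampled to pairwise |cos| ≤ 0.3 — the same separation
bound the distractors obey — which guarantees that each seed's planted
synonyms are strictly its nearest neighbors whenever the synonym band
clears the cross-talk floor. All vectors are unit-norm; generation is
bit-reproducible under the configured seed. The defaults mirror the
empirical pattern that true synonyms show high cosine and low
variability while unrelated terms scatter lower.

The annotation generator draws a reference label per item from a base
distribution (default uniform over the ten classes), then each annotator
copies it with the agreement probability (default 0.8) or else draws
from the reference label's row of a confusion kernel (default uniform
off-diagonal, i.e. never the reference). This makes the expected pairwise
kappa available in closed form by enumerating the label-pair joint
distribution, which the tests exploit. `annotate_candidates` applies the
same perturbation model to real retrieval output, with reference labels
derived from the planted roles (a planted synonym of the queried seed is
a synonym; a related term or another concept's term is a symptom/sign; a
distractor is "other").

The note generator writes lowercase alphanumeric filler words and, per
patient and concept, plants one of the concept's lexicon terms verbatim
at a word boundary with the cohort's prevalence probability. To guarantee
filler can never form a lexicon term — even across adjacent words — no
filler word may equal any *token* of any lexicon term, a slightly
stronger condition than whole-term disjointness. What the synthetic
corpus does **not** emulate: clinical-note grammar, negated or historical
mentions, misspellings, abbreviation ambiguity, or section structure.
Passing tests therefore demonstrate that the machinery (retrieval,
agreement arithmetic, matching, aggregation) is correct, not that the
lexicons would achieve any particular recall on real discharge
summaries.

## Pipeline defaults and problem sizes

The packaged demonstration uses 7 sources × 13 seed concepts (the
severity-relevant features), 5 synonyms + 5 related + 40 distractors per
source in 50 dimensions, k = 20, three annotators at agreement
probability 0.9, and three cohorts (pneumonia, ARDS, COVID-19) of 400
patients × 3 notes. Planted documentation prevalences emulate the
reported spread for these cohorts — fever 0.61/0.68/0.84, cough
0.41/0.46/0.55, shortness of breath 0.40/0.47/0.59, hypoxia around
0.51–0.56, and dry cough rare but highest in the COVID-19 cohort
(0.05/0.03/0.07) — with modest values for the remaining features. Test
configurations scale the same structure down (3 sources, tens of
patients) to keep the suite fast; stage seeds derive from the run seed
via `numpy.random.SeedSequence`, so every stage is a pure function of
(inputs, config, seed) and reruns are byte-identical, which the manifest
checksums make checkable.

## Known limitations

- Released FastText `.vec` files are treated as closed vocabularies; true
  subword composition for OOV queries is not implemented.
- The consensus rule, severe-group logic, and phrase-fallback strategy
  are documented defaults for genuinely under-specified choices; all
  three are parameters, not constants.
- Matching is surface-level by design; proportions measure
  documentation, not clinical assertion.
- Planted embedding spaces are isotropic apart from the planted
  structure; real embedding spaces have anisotropy and frequency effects
  that can distort cosine rankings.
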