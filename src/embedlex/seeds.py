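"""Seed clinical concepts for COVID-19 respiratory illness.

The query vocabulary: symptom, finding and disorder terms drawn from the
early-pandemic clinical literature, plus the modifier contrast pairs
(unmodified term vs qualified/anatomically-modified variants) used in the
source-profiling analyses.
"""

from __future__ import annotations

from .embeddings import QueryTerm

SYMPTOM_TERMS: tuple[str, ...] = (
    "fever",
    "high fever",
    "cough",
    "wet cough",
    "dry cough",
    "congestion",
    "nasal congestion",
    "pain",
    "chest pain",
    "muscle pain",
    "shortness of breath",
    "dyspnea",
    "tachypnea",
    "malaise",
    "headache",
    "sore throat",
)

FINDING_TERMS: tuple[str, ...] = (
    "hypoxia",
    "opacities",
    "bilateral opacities",
    "infiltrates",
    "lung infiltrates",
)

DISORDER_TERMS: tuple[str, ...] = (
    "ARDS",
    "respiratory distress",
    "acute respiratory distress syndrome",
    "pneumonia",
)

#: (category, unmodified term) -> modified variants.
MODIFIER_PAIRS: dict[str, tuple[str, ...]] = {
    "fever": ("high fever",),
    "cough": ("wet cough", "dry cough"),
    "congestion": ("nasal congestion",),
    "pain": ("chest pain", "muscle pain"),
    "opacities": ("bilateral opacities",),
    "infiltrates": ("lung infiltrates",),
    "ARDS": ("respiratory distress", "acute respiratory distress syndrome"),
}

_MODIFIED = {v for vs in MODIFIER_PAIRS.values() for v in vs}


def seed_query_terms() -> list[QueryTerm]:
    """All seed terms as QueryTerm records with category and modifier flag."""
    out: list[QueryTerm] = []
    for cat, terms in (
        ("symptom", SYMPTOM_TERMS),
        ("finding", FINDING_TERMS),
        ("disorder", DISORDER_TERMS),
    ):
        for t in terms:
            out.append(QueryTerm(surface=t, category=cat, has_modifier=t in _MODIFIED))
    return out


def query_category_map() -> dict[str, str]:
    """Query surface -> category, from the seed-list assignment."""
    return {q.surface: q.category for q in seed_query_terms()}


#: Seed concept -> seed term(s), for lexicon construction. Each queried
#: surface doubles as the seed term set of its own concept.
def seed_concepts() -> dict[str, set[str]]:
    return {q.surface: {q.surface} for q in seed_query_terms()}
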