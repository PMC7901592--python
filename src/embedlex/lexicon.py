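"""Lexicon expansion and extrinsic evaluation on clinical notes.

Builds an expanded concept lexicon from synonym-labeled retrieval
candidates (keywords + embedding expansion), matches lexicon terms in
patient notes with word-boundary semantics, reports per-cohort feature
documentation proportions, and rolls patients up to respiratory illness
severity groups.

Matching is deliberately surface-level: case-insensitive, word-boundary
delimited, contiguous phrases, with hyphen/underscore variants of
multi-word terms accepted. No stemming and no negation/severity/
temporality contextualization — documentation, not assertion, is what is
measured.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .agreement import Annotation
from .profiling import consensus_labels
from .semantics import SemanticType
from .textnorm import canonical_term


@dataclass(frozen=True)
class LexiconTerm:
    """One term of a concept's term set, with provenance."""

    term: str  # stored case-folded, space-delimited
    tag: str  # "seed" or "learned"
    sources: frozenset[str] = frozenset()


@dataclass
class Lexicon:
    """Concept name -> set of surface terms expressing it."""

    concepts: dict[str, dict[str, LexiconTerm]] = field(default_factory=dict)

    def add(self, concept: str, term: str, tag: str, sources: Iterable[str] = ()) -> None:
        key = canonical_term(term)
        if not key:
            raise ValueError(f"empty term for concept {concept!r}")
        bucket = self.concepts.setdefault(concept, {})
        if key in bucket:
            prev = bucket[key]
            bucket[key] = LexiconTerm(
                term=key,
                tag="seed" if "seed" in (prev.tag, tag) else tag,
                sources=prev.sources | frozenset(sources),
            )
        else:
            bucket[key] = LexiconTerm(term=key, tag=tag, sources=frozenset(sources))

    def terms(self, concept: str) -> set[str]:
        return set(self.concepts.get(concept, {}))

    def all_terms(self) -> set[str]:
        return {t for bucket in self.concepts.values() for t in bucket}

    def __iter__(self):
        return iter(self.concepts)

    def __len__(self) -> int:
        return len(self.concepts)


def build_expanded_lexicon(
    seed_concepts: Mapping[str, Iterable[str]],
    annotations: Sequence[Annotation] = (),
    *,
    include_rule: str = "consensus",
) -> Lexicon:
    """Expand seed term sets with synonym-labeled retrieval candidates.

    Each concept's term set becomes seeds plus every returned term whose
    label is synonym, pooled over all sources. Under the default
    ``include_rule="consensus"`` the majority (tie-broken) label decides;
    ``"any"`` admits a term any single annotator called a synonym. Terms
    are case-folded and delimiter-normalized; contributing source names
    are recorded.
    """
    lex = Lexicon()
    for concept, terms in seed_concepts.items():
        for t in terms:
            lex.add(concept, t, tag="seed")
    known_queries = set(seed_concepts)
    for ann in annotations:
        if ann.query not in known_queries:
            raise ValueError(f"annotation references unknown query term {ann.query!r}")
    if include_rule == "consensus":
        for item, cl in consensus_labels(annotations).items():
            query, returned, source = item
            if cl.label is SemanticType.SYNONYM:
                lex.add(query, returned, tag="learned", sources=[source])
    elif include_rule == "any":
        for ann in annotations:
            if ann.label is SemanticType.SYNONYM:
                lex.add(ann.query, ann.returned, tag="learned", sources=[ann.source_name])
    else:
        raise ValueError(f"unknown include_rule {include_rule!r}")
    return lex


# ---------------------------------------------------------------------------
# notes and matching


@dataclass(frozen=True)
class PatientNote:
    patient_id: str
    cohort: str
    note_text: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


_BOUNDARY_L = r"(?<![A-Za-z0-9])"
_BOUNDARY_R = r"(?![A-Za-z0-9])"


def term_pattern(term: str) -> re.Pattern:
    """Compiled pattern for one lexicon term.

    Case-insensitive, word-boundary delimited; the tokens of a multi-word
    term may be joined by a single space, hyphen or underscore (learned
    terms arrive in corpus-specific delimiter conventions).
    """
    tokens = canonical_term(term).split(" ")
    body = r"[ _\-]".join(re.escape(tok) for tok in tokens)
    return re.compile(_BOUNDARY_L + body + _BOUNDARY_R, flags=re.IGNORECASE)


def match_features(
    notes: Sequence[PatientNote], lexicon: Lexicon
) -> pd.DataFrame:
    """Per-patient, per-concept boolean table.

    A patient is positive for a concept iff any of their notes contains
    any of the concept's lexicon terms. Duplicate (patient, note text)
    rows are rejected; empty note text matches nothing. The returned
    frame is indexed by patient_id with a ``cohort`` column followed by
    one boolean column per concept.
    """
    if not len(lexicon):
        raise ValueError("lexicon is empty")
    seen: set[tuple[str, str]] = set()
    cohort_of: dict[str, str] = {}
    notes_of: dict[str, list[str]] = {}
    for note in notes:
        key = (note.patient_id, note.note_text)
        if key in seen:
            raise ValueError(f"duplicate note row for patient {note.patient_id!r}")
        seen.add(key)
        if cohort_of.setdefault(note.patient_id, note.cohort) != note.cohort:
            raise ValueError(f"patient {note.patient_id!r} assigned to multiple cohorts")
        notes_of.setdefault(note.patient_id, []).append(note.note_text)

    patterns = {
        concept: [term_pattern(t) for t in sorted(lexicon.terms(concept))]
        for concept in lexicon
    }
    patients = sorted(notes_of)
    records = []
    for pid in patients:
        row: dict[str, object] = {"cohort": cohort_of[pid]}
        text_blobs = notes_of[pid]
        for concept, pats in patterns.items():
            row[concept] = any(p.search(text) for text in text_blobs for p in pats)
        records.append(row)
    frame = pd.DataFrame(records, index=pd.Index(patients, name="patient_id"))
    return frame[["cohort"] + sorted(patterns)]


@dataclass(frozen=True)
class FeatureProportion:
    cohort: str
    concept: str
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator

    @property
    def rounded(self) -> float:
        return round(self.proportion, 2)


def feature_proportions(match_table: pd.DataFrame) -> list[FeatureProportion]:
    """Fraction of each cohort's patients with the feature documented in
    one or more notes. Exact numerator/denominator are carried alongside
    the 2-dp rounded value."""
    concepts = [c for c in match_table.columns if c != "cohort"]
    out: list[FeatureProportion] = []
    for cohort, group in match_table.groupby("cohort", sort=True):
        if len(group) == 0:
            raise ValueError(f"empty cohort {cohort!r}")
        for concept in concepts:
            out.append(
                FeatureProportion(
                    cohort=str(cohort),
                    concept=concept,
                    numerator=int(group[concept].sum()),
                    denominator=len(group),
                )
            )
    return out


# ---------------------------------------------------------------------------
# severity groups


@dataclass(frozen=True)
class SeverityGroup:
    """One severity group's combination rule: all ``required`` features
    positive AND (``any_of`` empty or at least one positive)."""

    name: str
    required: tuple[str, ...] = ()
    any_of: tuple[str, ...] = ()

    def features(self) -> set[str]:
        return set(self.required) | set(self.any_of)


@dataclass(frozen=True)
class SeverityGroupMap:
    groups: tuple[SeverityGroup, ...]


def default_severity_map() -> SeverityGroupMap:
    """Respiratory illness severity groups and their clinical features.

    Mild illness: any of fever, (dry) cough, sore throat, malaise,
    headache, muscle pain, nasal congestion. Moderate pneumonia: cough
    and shortness of breath. Severe pneumonia/ARDS: fever together with
    at least one of dyspnea, respiratory distress, tachypnea, hypoxia.
    The severe rule is one explicit reading of an ambiguous clinical
    description and is overridable by supplying a different map.
    """
    return SeverityGroupMap(
        groups=(
            SeverityGroup(
                name="mild illness",
                any_of=(
                    "fever",
                    "cough",
                    "sore throat",
                    "malaise",
                    "headache",
                    "muscle pain",
                    "nasal congestion",
                ),
            ),
            SeverityGroup(
                name="moderate pneumonia",
                required=("cough", "shortness of breath"),
            ),
            SeverityGroup(
                name="severe pneumonia/ARDS",
                required=("fever",),
                any_of=("dyspnea", "respiratory distress", "tachypnea", "hypoxia"),
            ),
        )
    )


def severity_rollup(
    match_table: pd.DataFrame, severity_map: SeverityGroupMap | None = None
) -> pd.DataFrame:
    """Per-patient severity-group flags; a patient may satisfy several
    groups and all satisfied groups are flagged."""
    if severity_map is None:
        severity_map = default_severity_map()
    concepts = set(match_table.columns) - {"cohort"}
    for group in severity_map.groups:
        unknown = group.features() - concepts
        if unknown:
            raise ValueError(
                f"severity group {group.name!r} references features missing "
                f"from the match table: {sorted(unknown)}"
            )
    out = pd.DataFrame(index=match_table.index)
    out["cohort"] = match_table["cohort"]
    for group in severity_map.groups:
        flag = pd.Series(True, index=match_table.index)
        for feat in group.required:
            flag &= match_table[feat]
        if group.any_of:
            flag &= match_table[list(group.any_of)].any(axis=1)
        out[group.name] = flag
    return out


# ---------------------------------------------------------------------------
# tabular I/O


def write_lexicon(lexicon: Lexicon, path: str | Path) -> Path:
    rows = []
    for concept in sorted(lexicon.concepts):
        for key in sorted(lexicon.concepts[concept]):
            t = lexicon.concepts[concept][key]
            rows.append(
                {
                    "concept": concept,
                    "term": t.term,
                    "tag": t.tag,
                    "sources": ";".join(sorted(t.sources)),
                }
            )
    pd.DataFrame(rows, columns=["concept", "term", "tag", "sources"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def read_lexicon(path: str | Path) -> Lexicon:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lex = Lexicon()
    for _, row in frame.iterrows():
        sources = [s for s in row["sources"].split(";") if s]
        lex.add(row["concept"], row["term"], tag=row["tag"], sources=sources)
    return lex


def write_notes(notes: Sequence[PatientNote], path: str | Path) -> Path:
    pd.DataFrame(
        [
            {"patient_id": n.patient_id, "cohort": n.cohort, "note_text": n.note_text}
            for n in notes
        ],
        columns=["patient_id", "cohort", "note_text"],
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_notes(path: str | Path) -> list[PatientNote]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        PatientNote(
            patient_id=row["patient_id"], cohort=row["cohort"], note_text=row["note_text"]
        )
        for _, row in frame.iterrows()
    ]


def proportions_to_frame(proportions: Sequence[FeatureProportion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cohort": p.cohort,
                "concept": p.concept,
                "numerator": p.numerator,
                "denominator": p.denominator,
                "proportion": p.rounded,
            }
            for p in proportions
        ],
        columns=["cohort", "concept", "numerator", "denominator", "proportion"],
    )
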