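"""Synthetic inputs with planted ground truth.

Every downstream stage of the pipeline is testable without the original
(proprietary or large) inputs because this module generates:

- embedding spaces with planted synonym / related / distractor clusters
  at controlled cosine separations from their seed terms,
- multi-annotator semantic labelings with a controlled per-annotator
  agreement probability and confusion kernel,
- note corpora with lexicon terms planted at specified per-cohort
  prevalences.

All generation is deterministic under the configured RNG seed: identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import Annotation
from .embeddings import EmbeddingSource
from .lexicon import Lexicon, PatientNote
from .neighbors import RankedCandidate
from .semantics import LABEL_ORDER, SemanticType
from .textnorm import canonical_term

_MAX_RESAMPLE = 1000  # distractor / seed-direction resampling cap
_DISTRACTOR_MAX_COS = 0.3


# ---------------------------------------------------------------------------
# embedding spaces


@dataclass(frozen=True)
class SynthEmbeddingConfig:
    """Controls one planted embedding space.

    ``target_cos_synonym``/``target_cos_related`` set the intended cosine
    of planted synonym / related vectors to their seed; each realized
    cosine is drawn uniformly within ``cos_jitter`` of its target.
    Distractors are near-orthogonal to every seed (|cos| <= 0.3 by
    check-and-resample).
    """

    seed_terms: tuple[str, ...]
    dimension: int = 50
    synonyms_per_seed: int = 5
    related_per_seed: int = 5
    distractor_count: int = 50
    target_cos_synonym: float = 0.9
    target_cos_related: float = 0.4
    cos_jitter: float = 0.05
    rng_seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2 to construct orthogonal complements")
        if not (0.0 < self.target_cos_synonym <= 1.0):
            raise ValueError("target_cos_synonym must lie in (0, 1]")
        if not (0.0 <= self.target_cos_related < 1.0):
            raise ValueError("target_cos_related must lie in [0, 1)")
        if self.target_cos_synonym <= self.target_cos_related:
            raise ValueError("target_cos_synonym must exceed target_cos_related")
        if self.cos_jitter < 0:
            raise ValueError("cos_jitter must be >= 0")
        if min(self.synonyms_per_seed, self.related_per_seed, self.distractor_count) < 0:
            raise ValueError("counts must be non-negative")
        if not self.seed_terms:
            raise ValueError("need at least one seed term")
        keys = [_seed_key(t) for t in self.seed_terms]
        if len(set(keys)) != len(keys):
            raise ValueError("seed terms must be unique after normalization")
        if any(not k for k in keys):
            raise ValueError("seed terms must be non-empty")


@dataclass
class PlantedTruth:
    """Ground truth of a generated space: each vocabulary term has exactly
    one role, and non-seed terms record their seed and intended cosine."""

    role: dict[str, str]  # term -> seed | synonym | related | distractor
    seed_of: dict[str, str]  # term -> its seed's vocabulary key (non-distractors)
    intended_cos: dict[str, float]  # term -> intended cosine to its seed

    def synonyms_of(self, seed_key: str) -> set[str]:
        return {
            t
            for t, r in self.role.items()
            if r == "synonym" and self.seed_of.get(t) == seed_key
        }


def _seed_key(term: str) -> str:
    """Vocabulary key of a seed phrase: case-folded, underscore-joined."""
    return "_".join(canonical_term(term).split(" "))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("degenerate zero draw")
    return v / n


def _orthogonal_unit(rng: np.random.Generator, u: np.ndarray) -> np.ndarray:
    """Unit vector orthogonal to ``u``: Gram-Schmidt on a standard-normal
    draw, resampling the (measure-zero) parallel case."""
    for _ in range(_MAX_RESAMPLE):
        r = rng.standard_normal(u.shape[0])
        r -= np.dot(r, u) * u
        n = np.linalg.norm(r)
        if n > 1e-9:
            return r / n
    raise ValueError(
        f"could not construct an orthogonal complement in dimension {u.shape[0]}"
    )


def _vector_at_cosine(
    rng: np.random.Generator, u: np.ndarray, target: float, jitter: float
) -> tuple[np.ndarray, float]:
    c = target if jitter == 0.0 else float(rng.uniform(target - jitter, target + jitter))
    c = float(np.clip(c, -1.0, 1.0))
    r = _orthogonal_unit(rng, u)
    return c * u + np.sqrt(max(0.0, 1.0 - c * c)) * r, c


def generate_embedding_space(
    config: SynthEmbeddingConfig,
) -> tuple[EmbeddingSource, PlantedTruth]:
    """Build a unit-norm embedding space with planted structure.

    Seeds are mutually near-orthogonal unit vectors (pairwise |cos| <=
    0.3 by check-and-resample, the same separation bound distractors
    obey), so each seed's planted synonyms are strictly its nearest
    neighbors whenever target_cos_synonym - cos_jitter exceeds the
    cross-talk floor. Synonym/related vectors are constructed as
    cos(theta) * u + sin(theta) * r with r orthogonal to the seed u, which
    forces the realized angle exactly.
    """
    rng = np.random.default_rng(config.rng_seed)
    seed_keys = [_seed_key(t) for t in config.seed_terms]

    seeds: list[np.ndarray] = []
    for key in seed_keys:
        for attempt in range(_MAX_RESAMPLE + 1):
            if attempt == _MAX_RESAMPLE:
                raise ValueError(
                    f"could not place seed {key!r} near-orthogonal to prior seeds "
                    f"in dimension {config.dimension}"
                )
            v = _unit(rng.standard_normal(config.dimension))
            if all(abs(np.dot(v, s)) <= _DISTRACTOR_MAX_COS for s in seeds):
                seeds.append(v)
                break

    vocab: list[str] = []
    vectors: list[np.ndarray] = []
    role: dict[str, str] = {}
    seed_of: dict[str, str] = {}
    intended: dict[str, float] = {}

    def add(term: str, vec: np.ndarray, r: str, seed: str | None, cos: float) -> None:
        if term in role:
            raise ValueError(f"duplicate term after normalization: {term!r}")
        vocab.append(term)
        vectors.append(vec)
        role[term] = r
        if seed is not None:
            seed_of[term] = seed
        intended[term] = cos

    for key, svec in zip(seed_keys, seeds):
        add(key, svec, "seed", key, 1.0)
    for key, svec in zip(seed_keys, seeds):
        for i in range(config.synonyms_per_seed):
            vec, c = _vector_at_cosine(rng, svec, config.target_cos_synonym, config.cos_jitter)
            add(f"{key}_syn{i + 1}", vec, "synonym", key, c)
        for i in range(config.related_per_seed):
            vec, c = _vector_at_cosine(rng, svec, config.target_cos_related, config.cos_jitter)
            add(f"{key}_rel{i + 1}", vec, "related", key, c)

    for i in range(config.distractor_count):
        for attempt in range(_MAX_RESAMPLE + 1):
            if attempt == _MAX_RESAMPLE:
                raise ValueError(
                    f"exceeded {_MAX_RESAMPLE} resampling attempts placing "
                    f"distractor {i + 1} in dimension {config.dimension}"
                )
            v = _unit(rng.standard_normal(config.dimension))
            if all(abs(np.dot(v, s)) <= _DISTRACTOR_MAX_COS for s in seeds):
                add(f"{config.name}_dis{i + 1}", v, "distractor", None, 0.0)
                break

    source = EmbeddingSource(
        name=config.name,
        vocabulary=vocab,
        vectors=np.array(vectors),
        unit="token",
        case_policy="lowercase",
        phrase_policy="multiword_keys",
        metadata={"synthetic": True, "rng_seed": config.rng_seed},
    )
    return source, PlantedTruth(role=role, seed_of=seed_of, intended_cos=intended)


def write_truth(truth: PlantedTruth, path: str | Path) -> Path:
    rows = [
        {
            "term": t,
            "role": truth.role[t],
            "seed": truth.seed_of.get(t, ""),
            "intended_cos": f"{truth.intended_cos[t]:.6f}",
        }
        for t in sorted(truth.role)
    ]
    pd.DataFrame(rows, columns=["term", "role", "seed", "intended_cos"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


# ---------------------------------------------------------------------------
# annotation sets


def uniform_base() -> dict[SemanticType, float]:
    return {lab: 1.0 / len(LABEL_ORDER) for lab in LABEL_ORDER}


def uniform_offdiagonal_kernel() -> np.ndarray:
    """Row-stochastic kernel that never returns the reference label."""
    n = len(LABEL_ORDER)
    k = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(k, 0.0)
    return k


@dataclass(frozen=True)
class SynthAnnotationConfig:
    """Label model: per item a reference label is drawn from
    ``base_labels``; each annotator copies it with probability
    ``agreement_prob``, otherwise draws from the reference label's row of
    ``confusion_kernel``."""

    item_count: int
    annotator_ids: tuple[str, ...] = ("a1", "a2", "a3")
    base_labels: Mapping[SemanticType, float] = field(default_factory=uniform_base)
    confusion_kernel: np.ndarray = field(default_factory=uniform_offdiagonal_kernel)
    agreement_prob: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.item_count < 1:
            raise ValueError("item_count must be positive")
        if len(self.annotator_ids) < 2:
            raise ValueError("need at least 2 annotators")
        if not (0.0 <= self.agreement_prob <= 1.0):
            raise ValueError("agreement_prob must lie in [0, 1]")
        kernel = np.asarray(self.confusion_kernel, dtype=np.float64)
        if kernel.shape != (len(LABEL_ORDER), len(LABEL_ORDER)):
            raise ValueError(f"confusion_kernel must be {len(LABEL_ORDER)}x{len(LABEL_ORDER)}")
        if not np.allclose(kernel.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion_kernel rows must sum to 1 (tolerance 1e-9)")
        base = np.array([self.base_labels.get(lab, 0.0) for lab in LABEL_ORDER])
        if not np.isclose(base.sum(), 1.0, atol=1e-9) or np.any(base < 0):
            raise ValueError("base_labels must be a distribution over the label set")


def generate_annotation_set(
    config: SynthAnnotationConfig, *, return_truth: bool = False
):
    """Simulate multi-annotator labels for synthetic items.

    Items are keyed ("q", "t<i>", "synthetic"). With ``return_truth`` the
    per-item reference labels are returned alongside the annotations.
    """
    rng = np.random.default_rng(config.rng_seed)
    base = np.array([config.base_labels.get(lab, 0.0) for lab in LABEL_ORDER])
    base = base / base.sum()
    kernel = np.asarray(config.confusion_kernel, dtype=np.float64)

    refs = rng.choice(len(LABEL_ORDER), size=config.item_count, p=base)
    annotations: list[Annotation] = []
    truth: dict[tuple[str, str, str], SemanticType] = {}
    for i, ref in enumerate(refs):
        item = ("q", f"t{i:05d}", "synthetic")
        truth[item] = LABEL_ORDER[ref]
        for annotator in config.annotator_ids:
            if rng.random() < config.agreement_prob:
                lab = int(ref)
            else:
                lab = int(rng.choice(len(LABEL_ORDER), p=kernel[ref]))
            annotations.append(
                Annotation(
                    query=item[0],
                    returned=item[1],
                    source_name=item[2],
                    annotator_id=annotator,
                    label=LABEL_ORDER[lab],
                )
            )
    if return_truth:
        return annotations, truth
    return annotations


_ROLE_REFERENCE_LABEL = {
    "synonym": SemanticType.SYNONYM,
    "related": SemanticType.SYMPTOM_SIGN,
    "seed": SemanticType.SYMPTOM_SIGN,  # another seed concept, not a synonym
    "distractor": SemanticType.OTHER,
}


def annotate_candidates(
    candidates: Sequence[RankedCandidate],
    truths: Mapping[str, PlantedTruth],
    annotator_ids: Sequence[str],
    agreement_prob: float,
    rng_seed: int,
    confusion_kernel: np.ndarray | None = None,
) -> list[Annotation]:
    """Simulate annotators labeling real retrieval output.

    Reference labels come from the planted roles (a planted synonym of
    the queried seed is a synonym; a related term or a different seed is
    a symptom/sign; a distractor is "other"); each annotator then copies
    or confuses the reference exactly as in generate_annotation_set.
    ``truths`` maps source name -> planted truth for that source.
    """
    if len(annotator_ids) < 2:
        raise ValueError("need at least 2 annotators")
    kernel = (
        uniform_offdiagonal_kernel() if confusion_kernel is None else np.asarray(confusion_kernel)
    )
    rng = np.random.default_rng(rng_seed)
    idx = {lab: i for i, lab in enumerate(LABEL_ORDER)}
    out: list[Annotation] = []
    for cand in candidates:
        truth = truths[cand.source_name]
        role = truth.role.get(cand.returned, "distractor")
        ref = _ROLE_REFERENCE_LABEL[role]
        if role == "synonym" and truth.seed_of.get(cand.returned) != _seed_key(cand.query):
            ref = SemanticType.SYMPTOM_SIGN  # synonym of a different concept
        ref_i = idx[ref]
        for annotator in annotator_ids:
            if rng.random() < agreement_prob:
                lab = ref_i
            else:
                lab = int(rng.choice(len(LABEL_ORDER), p=kernel[ref_i]))
            out.append(
                Annotation(
                    query=cand.query,
                    returned=cand.returned,
                    source_name=cand.source_name,
                    annotator_id=annotator,
                    label=LABEL_ORDER[lab],
                )
            )
    return out


# ---------------------------------------------------------------------------
# note corpora


DEFAULT_FILLER: tuple[str, ...] = (
    "patient", "reports", "denies", "states", "notes", "history", "exam",
    "stable", "normal", "review", "plan", "continue", "follow", "discussed",
    "today", "morning", "evening", "prior", "during", "admission",
)


@dataclass(frozen=True)
class SynthCohortConfig:
    """Planted note corpus: for each patient and concept, with the
    cohort's prevalence probability at least one lexicon term for the
    concept is embedded verbatim in one of the patient's notes."""

    cohorts: tuple[tuple[str, int], ...]
    concept_prevalence: Mapping[str, Mapping[str, float]]  # cohort -> concept -> p
    filler_vocabulary: tuple[str, ...] = DEFAULT_FILLER
    notes_per_patient: int = 3
    words_per_note: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        names = [c for c, _ in self.cohorts]
        if len(set(names)) != len(names):
            raise ValueError("cohort names must be unique")
        if any(n < 1 for _, n in self.cohorts):
            raise ValueError("patient counts must be positive")
        if self.notes_per_patient < 1:
            raise ValueError("notes_per_patient must be positive")
        for cohort, prevs in self.concept_prevalence.items():
            if cohort not in names:
                raise ValueError(f"prevalence given for unknown cohort {cohort!r}")
            for concept, p in prevs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prevalence for {cohort!r}/{concept!r} outside [0, 1]")


def generate_cohort_notes(
    config: SynthCohortConfig, lexicon: Lexicon
) -> list[PatientNote]:
    """Plant lexicon terms in filler notes at per-cohort prevalences.

    Filler text is lowercase alphanumeric words; to guarantee filler can
    never form a lexicon term (even across adjacent words), no filler
    word may equal any token of any lexicon term. Planted terms are
    inserted verbatim at word boundaries. Deterministic under rng_seed.
    """
    lex_tokens = {tok for term in lexicon.all_terms() for tok in term.split(" ")}
    overlap = {w for w in config.filler_vocabulary if canonical_term(w) in lex_tokens}
    if overlap:
        raise ValueError(
            f"filler vocabulary overlaps lexicon term tokens: {sorted(overlap)}"
        )
    for cohort, prevs in config.concept_prevalence.items():
        for concept in prevs:
            if concept not in lexicon.concepts:
                raise ValueError(f"prevalence for unknown concept {concept!r}")

    rng = np.random.default_rng(config.rng_seed)
    filler = list(config.filler_vocabulary)
    notes: list[PatientNote] = []
    for cohort, n_patients in config.cohorts:
        prevs = dict(config.concept_prevalence.get(cohort, {}))
        for i in range(n_patients):
            pid = f"{cohort}_{i:05d}"
            texts = [
                [filler[j] for j in rng.integers(0, len(filler), size=config.words_per_note)]
                for _ in range(config.notes_per_patient)
            ]
            for concept in sorted(prevs):
                p = prevs[concept]
                if rng.random() < p:
                    terms = sorted(lexicon.terms(concept))
                    term = terms[int(rng.integers(0, len(terms)))]
                    note_i = int(rng.integers(0, config.notes_per_patient))
                    pos = int(rng.integers(0, len(texts[note_i]) + 1))
                    texts[note_i].insert(pos, term)
            for words in texts:
                notes.append(PatientNote(patient_id=pid, cohort=cohort, note_text=" ".join(words)))
    return notes
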