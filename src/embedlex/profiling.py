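"""Cross-source aggregation of candidate lists and annotations.

Word-cloud frequency weights (how many of the S sources returned a term,
divided by S), consensus semantic labels, per-(source, query) semantic
type distributions, group mean counts, and modifier contrasts between
qualified and unqualified query variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .agreement import Annotation, ItemKey
from .neighbors import RankedCandidate
from .semantics import CONSENSUS_PRIORITY, LABEL_ORDER, SemanticType
from .textnorm import canonical_term


@dataclass(frozen=True)
class SourceFrequencyWeight:
    """A returned term's presence count across sources over the source count.

    For S = 7 the weight is bounded between 1/7 = 0.14 (term observed in a
    single source) and 1.0 (observed in all seven).
    """

    term: str
    source_count: int
    total_sources: int

    @property
    def weight(self) -> float:
        return self.source_count / self.total_sources


def frequency_weights(
    top_k_lists: Mapping[str, Sequence[RankedCandidate]],
) -> list[SourceFrequencyWeight]:
    """Word-cloud weights for one query across per-source top-k lists.

    A term counts for a source if it appears at any rank in that source's
    list; term identity is case/delimiter-insensitive. One record per
    unique returned term, sorted by descending weight then term.
    """
    total = len(top_k_lists)
    if total < 1:
        raise ValueError("need at least one source")
    presence: dict[str, set[str]] = {}
    surface: dict[str, str] = {}
    for source_name, candidates in top_k_lists.items():
        for cand in candidates:
            key = canonical_term(cand.returned)
            presence.setdefault(key, set()).add(source_name)
            surface.setdefault(key, cand.returned)
    records = [
        SourceFrequencyWeight(term=surface[key], source_count=len(srcs), total_sources=total)
        for key, srcs in presence.items()
    ]
    records.sort(key=lambda r: (-r.weight, canonical_term(r.term)))
    return records


# ---------------------------------------------------------------------------
# consensus labels


@dataclass(frozen=True)
class ConsensusLabel:
    label: SemanticType
    tie_broken: bool


def consensus_label(labels: Sequence[SemanticType]) -> ConsensusLabel:
    """Majority label across annotators for one item.

    Ties are broken by a fixed priority order (synonym > negation >
    hypernym > hyponym > symptom/sign > disease/disorder > qualifier >
    anatomical location > therapeutic > other) and flagged.
    """
    if not labels:
        raise ValueError("need at least one annotator label")
    counts: dict[SemanticType, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == best]
    if len(tied) == 1:
        return ConsensusLabel(tied[0], tie_broken=False)
    winner = min(tied, key=CONSENSUS_PRIORITY.index)
    return ConsensusLabel(winner, tie_broken=True)


def consensus_labels(
    annotations: Iterable[Annotation],
) -> dict[ItemKey, ConsensusLabel]:
    """Consensus label per (query, returned, source) item."""
    grouped: dict[ItemKey, list[SemanticType]] = {}
    for ann in annotations:
        grouped.setdefault(ann.item, []).append(ann.label)
    return {item: consensus_label(labs) for item, labs in grouped.items()}


# ---------------------------------------------------------------------------
# semantic-type distributions


@dataclass
class SemanticDistribution:
    """Counts per semantic type among one (source, query)'s candidates."""

    source_name: str
    query: str
    counts: dict[SemanticType, int] = field(
        default_factory=lambda: {lab: 0 for lab in LABEL_ORDER}
    )
    tie_count: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def semantic_type_distribution(
    annotations: Sequence[Annotation],
    top_k_lists: Mapping[str, Mapping[str, Sequence[RankedCandidate]]],
) -> list[SemanticDistribution]:
    """Distribution of consensus semantic types per (source, query).

    ``top_k_lists`` maps source name -> query surface -> candidate list.
    Every candidate must have a consensus label; unlabeled candidates are
    an error (they would silently shrink the distribution).
    """
    labels = consensus_labels(annotations)
    out: list[SemanticDistribution] = []
    missing: list[ItemKey] = []
    for source_name in sorted(top_k_lists):
        per_query = top_k_lists[source_name]
        for query in sorted(per_query):
            dist = SemanticDistribution(source_name=source_name, query=query)
            for cand in per_query[query]:
                item = (query, cand.returned, source_name)
                if item not in labels:
                    missing.append(item)
                    continue
                cl = labels[item]
                dist.counts[cl.label] += 1
                dist.tie_count += int(cl.tie_broken)
            out.append(dist)
    if missing:
        raise ValueError(
            f"{len(missing)} candidates without annotations, e.g. {missing[:5]}"
        )
    return out


def mean_type_count(
    distributions: Sequence[SemanticDistribution],
    source_group: Iterable[str],
    semantic_type: SemanticType,
) -> float:
    """Mean count of one semantic type over (source in group, query) cells,
    rounded to 2 decimal places."""
    group = set(source_group)
    if not group:
        raise ValueError("source group must be non-empty")
    cells = [d.counts[semantic_type] for d in distributions if d.source_name in group]
    if not cells:
        raise ValueError(f"no distributions for sources {sorted(group)}")
    return round(sum(cells) / len(cells), 2)


# ---------------------------------------------------------------------------
# modifier contrasts


@dataclass(frozen=True)
class ModifierContrast:
    """Mean semantic-type counts for a modified vs unmodified query pair."""

    unmodified: str
    modified: str
    semantic_type: SemanticType
    mean_modified: float
    mean_unmodified: float

    @property
    def difference(self) -> float:
        return round(self.mean_modified - self.mean_unmodified, 2)


def modifier_contrast(
    distributions: Sequence[SemanticDistribution],
    pairs: Mapping[str, Sequence[str]] | None = None,
) -> list[ModifierContrast]:
    """Per admitted (unmodified, modified) pair and semantic type, the mean
    count across sources for each variant and their difference.

    Only the packaged modifier pairs are admitted by default, restricted
    to the pairs whose variants actually occur among the distributions.
    When an explicit ``pairs`` mapping is supplied, a missing variant is
    an error naming it.
    """
    by_query: dict[str, list[SemanticDistribution]] = {}
    for d in distributions:
        by_query.setdefault(d.query, []).append(d)
    if pairs is None:
        from .seeds import MODIFIER_PAIRS

        pairs = {
            unmod: tuple(v for v in variants if v in by_query)
            for unmod, variants in MODIFIER_PAIRS.items()
            if unmod in by_query
        }
        pairs = {u: vs for u, vs in pairs.items() if vs}

    def mean_counts(query: str) -> dict[SemanticType, float]:
        cells = by_query.get(query)
        if not cells:
            raise ValueError(f"no distributions for query variant {query!r}")
        return {
            lab: round(sum(d.counts[lab] for d in cells) / len(cells), 2)
            for lab in LABEL_ORDER
        }

    out: list[ModifierContrast] = []
    for unmod in sorted(pairs):
        base = mean_counts(unmod)
        for mod in pairs[unmod]:
            modified = mean_counts(mod)
            for lab in LABEL_ORDER:
                out.append(
                    ModifierContrast(
                        unmodified=unmod,
                        modified=mod,
                        semantic_type=lab,
                        mean_modified=modified[lab],
                        mean_unmodified=base[lab],
                    )
                )
    return out


# ---------------------------------------------------------------------------
# grid size


def annotation_grid_size(
    query_terms: int | Sequence,
    sources: int | Sequence,
    k: int,
    annotators: int | Sequence,
) -> int:
    """Number of annotation cells: k candidates x queries x sources x
    annotators. Arguments may be counts or the collections themselves."""

    def count(x) -> int:
        return x if isinstance(x, int) else len(x)

    nq, ns, na = count(query_terms), count(sources), count(annotators)
    if min(nq, ns, na, k) < 1:
        raise ValueError("all counts must be positive")
    return k * nq * ns * na


# ---------------------------------------------------------------------------
# tabular exports


def weights_to_frame(weights: Sequence[SourceFrequencyWeight]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": w.term, "source_count": w.source_count, "weight": round(w.weight, 6)}
            for w in weights
        ],
        columns=["term", "source_count", "weight"],
    )


def distributions_to_frame(distributions: Sequence[SemanticDistribution]) -> pd.DataFrame:
    rows = []
    for d in distributions:
        row = {"source": d.source_name, "query": d.query}
        row.update({lab.value: d.counts[lab] for lab in LABEL_ORDER})
        row["ties"] = d.tie_count
        rows.append(row)
    cols = ["source", "query"] + [lab.value for lab in LABEL_ORDER] + ["ties"]
    return pd.DataFrame(rows, columns=cols)


def contrasts_to_frame(contrasts: Sequence[ModifierContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unmodified": c.unmodified,
                "modified": c.modified,
                "semantic_type": c.semantic_type.value,
                "mean_modified": c.mean_modified,
                "mean_unmodified": c.mean_unmodified,
                "difference": c.difference,
            }
            for c in contrasts
        ],
        columns=[
            "unmodified",
            "modified",
            "semantic_type",
            "mean_modified",
            "mean_unmodified",
            "difference",
        ],
    )


def write_frame(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path
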