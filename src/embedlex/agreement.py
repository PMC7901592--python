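"""Interannotator agreement over the ten-class semantic scheme.

Pairwise Cohen kappa is computed per annotator pair, stratified either by
seed-term category (symptom / finding / disorder) or by individual query
term, together with 10x10 disagreement count matrices.

kappa = (p_o - p_e) / (1 - p_e), where p_o is the observed fraction of
items on which the two annotators agree and p_e the chance agreement
implied by their marginal label frequencies. The degenerate case p_e = 1
(both annotators concentrated on a single identical label) returns 1.0
when p_o = 1 and 0.0 otherwise, keeping perfect agreement reportable for
single-label strata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .semantics import LABEL_ORDER, SemanticType, parse_label

ItemKey = tuple[str, str, str]  # (query, returned, source)


@dataclass(frozen=True)
class Annotation:
    """One annotator's semantic-class label for one retrieval record."""

    query: str
    returned: str
    source_name: str
    annotator_id: str
    label: SemanticType

    @property
    def item(self) -> ItemKey:
        return (self.query, self.returned, self.source_name)


@dataclass
class AgreementReport:
    """Kappa and confusion counts for one annotator pair in one stratum."""

    annotator_pair: tuple[str, str]
    stratum: str
    kappa: float
    item_count: int
    confusion: np.ndarray  # 10x10, rows = first annotator, cols = second

    @property
    def observed_agreement(self) -> float:
        return float(np.trace(self.confusion)) / self.item_count


def cohen_kappa(
    labels_a: Sequence[SemanticType | str],
    labels_b: Sequence[SemanticType | str],
    label_set: Sequence[SemanticType] = LABEL_ORDER,
) -> float:
    """Chance-corrected agreement between two equal-length label sequences.

    Computed over the full closed label set even when some labels are
    unobserved. Symmetric in its two arguments; invariant under item
    permutation.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(f"length mismatch: {len(labels_a)} vs {len(labels_b)}")
    if len(labels_a) == 0:
        raise ValueError("cannot compute kappa on empty input")
    a = [parse_label(x) for x in labels_a]
    b = [parse_label(x) for x in labels_b]
    allowed = set(label_set)
    for lab in itertools.chain(a, b):
        if lab not in allowed:
            raise ValueError(f"label {lab} outside the provided label set")
    n = len(a)
    idx = {lab: i for i, lab in enumerate(label_set)}
    conf = np.zeros((len(label_set), len(label_set)), dtype=np.int64)
    for la, lb in zip(a, b):
        conf[idx[la], idx[lb]] += 1
    p_o = float(np.trace(conf)) / n
    p_e = float(np.dot(conf.sum(axis=1), conf.sum(axis=0))) / (n * n)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _align_pair(
    annotations: Iterable[Annotation], pair: tuple[str, str]
) -> tuple[list[SemanticType], list[SemanticType], list[ItemKey]]:
    """Align a pair's labels by (query, returned, source) item key."""
    first: dict[ItemKey, SemanticType] = {}
    second: dict[ItemKey, SemanticType] = {}
    for ann in annotations:
        if ann.annotator_id == pair[0]:
            target = first
        elif ann.annotator_id == pair[1]:
            target = second
        else:
            continue
        if ann.item in target:
            raise ValueError(
                f"duplicate annotation for item {ann.item} by annotator {ann.annotator_id!r}"
            )
        target[ann.item] = ann.label
    missing = set(first) ^ set(second)
    if missing:
        listed = sorted(missing)[:10]
        raise ValueError(
            f"{len(missing)} items labeled by only one annotator of pair {pair}: {listed}"
        )
    keys = sorted(first)
    return [first[k] for k in keys], [second[k] for k in keys], keys


def disagreement_matrix(
    annotations: Iterable[Annotation], pair: tuple[str, str]
) -> np.ndarray:
    """10x10 count matrix: entry (r, c) counts items the first annotator of
    the pair labeled ``LABEL_ORDER[r]`` and the second ``LABEL_ORDER[c]``."""
    a, b, _ = _align_pair(annotations, pair)
    idx = {lab: i for i, lab in enumerate(LABEL_ORDER)}
    conf = np.zeros((len(LABEL_ORDER), len(LABEL_ORDER)), dtype=np.int64)
    for la, lb in zip(a, b):
        conf[idx[la], idx[lb]] += 1
    return conf


def pairwise_agreement(
    annotations: Sequence[Annotation],
    strata: Literal["by_category", "by_query_term"],
    category_map: Mapping[str, str] | None = None,
) -> list[AgreementReport]:
    """One agreement report per (annotator pair, stratum).

    ``by_query_term`` strata are the query surfaces themselves;
    ``by_category`` strata come from the seed-list assignment supplied in
    ``category_map`` (query surface -> category). The packaged seed lists
    provide the default map.
    """
    annotators = sorted({a.annotator_id for a in annotations})
    if len(annotators) < 2:
        raise ValueError("need at least two annotators")
    if strata == "by_category":
        if category_map is None:
            from .seeds import query_category_map

            category_map = query_category_map()
        unknown = {a.query for a in annotations} - set(category_map)
        if unknown:
            raise ValueError(f"queries without category assignment: {sorted(unknown)[:10]}")
        stratum_of = lambda ann: category_map[ann.query]  # noqa: E731
    elif strata == "by_query_term":
        stratum_of = lambda ann: ann.query  # noqa: E731
    else:
        raise ValueError(f"unknown strata {strata!r}")

    groups: dict[str, list[Annotation]] = {}
    for ann in annotations:
        groups.setdefault(stratum_of(ann), []).append(ann)

    reports: list[AgreementReport] = []
    idx = {lab: i for i, lab in enumerate(LABEL_ORDER)}
    for stratum in sorted(groups):
        for pair in itertools.combinations(annotators, 2):
            a, b, keys = _align_pair(groups[stratum], pair)
            if not keys:
                continue
            conf = np.zeros((len(LABEL_ORDER), len(LABEL_ORDER)), dtype=np.int64)
            for la, lb in zip(a, b):
                conf[idx[la], idx[lb]] += 1
            reports.append(
                AgreementReport(
                    annotator_pair=pair,
                    stratum=stratum,
                    kappa=cohen_kappa(a, b),
                    item_count=len(keys),
                    confusion=conf,
                )
            )
    return reports


# ---------------------------------------------------------------------------
# tabular I/O

ANNOTATION_COLUMNS = ["query", "returned", "source", "annotator", "label"]


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "query": a.query,
                "returned": a.returned,
                "source": a.source_name,
                "annotator": a.annotator_id,
                "label": a.label.value,
            }
            for a in annotations
        ],
        columns=ANNOTATION_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_annotations(path: str | Path) -> list[Annotation]:
    """Load a TSV annotation table; duplicate (item, annotator) rows are
    rejected rather than silently overwritten."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = frame.duplicated(subset=["query", "returned", "source", "annotator"])
    if dup.any():
        rows = frame.loc[dup, ["query", "returned", "source", "annotator"]].head(5)
        raise ValueError(f"{path}: duplicate annotation rows, e.g.\n{rows}")
    return [
        Annotation(
            query=row["query"],
            returned=row["returned"],
            source_name=row["source"],
            annotator_id=row["annotator"],
            label=parse_label(row["label"]),
        )
        for _, row in frame.iterrows()
    ]


def reports_to_frame(reports: Sequence[AgreementReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "annotator_a": r.annotator_pair[0],
                "annotator_b": r.annotator_pair[1],
                "stratum": r.stratum,
                "kappa": round(r.kappa, 6),
                "items": r.item_count,
            }
            for r in reports
        ],
        columns=["annotator_a", "annotator_b", "stratum", "kappa", "items"],
    )


def matrix_to_frame(matrix: np.ndarray) -> pd.DataFrame:
    labels = [lab.value for lab in LABEL_ORDER]
    return pd.DataFrame(matrix, index=labels, columns=labels)
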