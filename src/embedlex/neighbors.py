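"""Cosine nearest-neighbor retrieval over embedding sources.

For each query term the source vocabulary is ranked by cosine similarity
(values closest to 1.0 signifying highest similarity) and the top-k
candidates are returned, excluding every normalized form of the query
itself. A cross-source comparison records, for one returned term, its
cosine in each source's top-k list with a sentinel of -1 where the term
was not retrieved by that source.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingSource, QueryTerm, normalize_query
from .textnorm import canonical_term

#: Sentinel cosine for a term absent from a source's top-k list.
ABSENT = -1.0

#: Default list depth.
DEFAULT_K = 20


@dataclass(frozen=True)
class RankedCandidate:
    """One (query, returned term) retrieval record."""

    query: str
    returned: str
    cosine: float
    rank: int
    source_name: str


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity: inner product over the product of norms.

    Raises on zero-norm input; the result is clipped to [-1, 1] to absorb
    floating-point overshoot.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"vector lengths differ: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _resolve_query_vector(
    source: EmbeddingSource,
    query: QueryTerm | str,
    phrase_strategy: Literal["key_only", "key_then_average"],
) -> tuple[np.ndarray, set[str]]:
    """Resolve a query to a vector and the set of probed vocabulary keys.

    Under ``key_then_average``, a multi-word query with no whole-phrase
    vocabulary key falls back to the unweighted mean of its constituent
    token vectors (each token normalized per source).
    """
    surface = query.surface if isinstance(query, QueryTerm) else query
    keys = normalize_query(surface, source)
    if keys:
        return source.vector(keys[0]), set(keys)
    if phrase_strategy == "key_then_average":
        tokens = surface.split()
        if len(tokens) > 1:
            vecs = []
            probed: set[str] = set()
            missing = []
            for tok in tokens:
                tok_keys = normalize_query(tok, source)
                if not tok_keys:
                    missing.append(tok)
                else:
                    vecs.append(source.vector(tok_keys[0]))
                    probed.update(tok_keys)
            if missing:
                raise KeyError(
                    f"query {surface!r} unresolvable in source {source.name!r}: "
                    f"tokens {missing} not in vocabulary"
                )
            return np.mean(vecs, axis=0), probed
    raise KeyError(
        f"query {surface!r} unresolvable in source {source.name!r} "
        f"under strategy {phrase_strategy!r}"
    )


def top_k_neighbors(
    source: EmbeddingSource,
    query: QueryTerm | str,
    k: int = DEFAULT_K,
    phrase_strategy: Literal["key_only", "key_then_average"] = "key_then_average",
) -> list[RankedCandidate]:
    """Rank the source vocabulary by cosine to the query; return the top k.

    All probed normalized forms of the query are excluded from the
    ranking (preventing trivial self-returns such as case or delimiter
    variants). Ties in cosine are broken lexicographically on the
    returned key. Returns ``min(k, |vocabulary| - |probed keys|)``
    candidates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    surface = query.surface if isinstance(query, QueryTerm) else query
    qvec, probed = _resolve_query_vector(source, query, phrase_strategy)

    norms = _source_norms(source)
    qnorm = np.linalg.norm(qvec)
    if qnorm == 0.0:
        raise ValueError(f"query {surface!r} resolves to a zero vector")
    sims = source.vectors @ qvec / (norms * qnorm)
    np.clip(sims, -1.0, 1.0, out=sims)

    mask = np.ones(len(source), dtype=bool)
    for key in probed:
        mask[source.index_of(key)] = False
    idx = np.nonzero(mask)[0]
    # sort by descending cosine, ties broken by lexicographic key
    keys = np.array(source.vocabulary, dtype=object)[idx]
    order = np.lexsort((keys, -sims[idx]))
    take = order[: min(k, len(idx))]
    return [
        RankedCandidate(
            query=surface,
            returned=str(keys[j]),
            cosine=float(sims[idx[j]]),
            rank=r + 1,
            source_name=source.name,
        )
        for r, j in enumerate(take)
    ]


def _source_norms(source: EmbeddingSource) -> np.ndarray:
    # norms precomputed once per source and cached on the instance
    norms = getattr(source, "_norms", None)
    if norms is None or len(norms) != len(source):
        norms = np.linalg.norm(source.vectors, axis=1)
        if np.any(norms == 0.0):
            zero = [source.vocabulary[i] for i in np.nonzero(norms == 0.0)[0][:5]]
            raise ValueError(f"source {source.name!r} has zero-norm vectors, e.g. {zero}")
        source._norms = norms  # type: ignore[attr-defined]
    return norms


@dataclass(frozen=True)
class CrossSourceCosine:
    """Per-source cosine of one returned term, -1 where absent."""

    term: str
    values: dict[str, float]  # source name -> cosine or ABSENT


def cross_source_cosines(
    term: str,
    top_k_lists: dict[str, Sequence[RankedCandidate]],
) -> CrossSourceCosine:
    """Look up one returned term across the per-source top-k lists.

    Term identity is delimiter/case-insensitive so that "dry_cough" in
    one source matches "dry-cough" in another. Sources whose list does
    not contain the term receive the sentinel -1.
    """
    target = canonical_term(term)
    values: dict[str, float] = {}
    for source_name, candidates in top_k_lists.items():
        values[source_name] = ABSENT
        for cand in candidates:
            if canonical_term(cand.returned) == target:
                values[source_name] = cand.cosine
                break
    return CrossSourceCosine(term=term, values=values)


# ---------------------------------------------------------------------------
# tabular export


def candidates_to_frame(candidates: Sequence[RankedCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": c.query,
                "returned": c.returned,
                "cosine": round(c.cosine, 6),
                "rank": c.rank,
                "source": c.source_name,
            }
            for c in candidates
        ],
        columns=["query", "returned", "cosine", "rank", "source"],
    )


def write_candidates(candidates: Sequence[RankedCandidate], path: str | Path) -> Path:
    """Export candidate lists as TSV: query, returned, cosine (6 dp), rank, source."""
    path = Path(path)
    frame = candidates_to_frame(candidates)
    frame["cosine"] = frame["cosine"].map(lambda x: f"{x:.6f}")
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_candidates(path: str | Path) -> list[RankedCandidate]:
    frame = pd.read_csv(path, sep="\t", dtype={"query": str, "returned": str, "source": str})
    return [
        RankedCandidate(
            query=row["query"],
            returned=row["returned"],
            cosine=float(row["cosine"]),
            rank=int(row["rank"]),
            source_name=row["source"],
        )
        for _, row in frame.iterrows()
    ]
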