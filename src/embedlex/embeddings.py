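"""Reading, writing and probing word-embedding sources.

Supports the four file dialects in which public embedding releases
circulate:

- ``word2vec_text``: first line ``"<count> <dim>"``, then one
  ``key v1 ... vd`` row per term.
- ``word2vec_binary``: same header line, then ``key`` + space + ``dim``
  little-endian float32 values per term.
- ``glove_text``: headerless rows; the dimension is inferred from the
  first row.
- ``fasttext_vec``: the released ``.vec`` text format, structurally
  identical to ``word2vec_text`` (subword inference is out of scope; the
  file is treated as a fixed lookup table).

Each loaded source carries construction metadata (unit, case policy,
phrase policy) so queries can be normalized per source: a source built
lowercase must be probed with lowercase keys, and multi-word queries must
be probed in the delimiter convention of that release.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

Dialect = Literal["word2vec_text", "word2vec_binary", "glove_text", "fasttext_vec"]
DIALECTS: tuple[str, ...] = (
    "word2vec_text",
    "word2vec_binary",
    "glove_text",
    "fasttext_vec",
)


@dataclass
class EmbeddingSource:
    """A named vocabulary-to-vector map plus construction metadata.

    Parameters
    ----------
    name:
        Source identifier (e.g. "bioasq").
    unit:
        Whether vectors were trained on whole tokens or character
        n-grams; character-unit sources tend to return lexical variants.
    vocabulary:
        Ordered unique keys.
    vectors:
        ``(len(vocabulary), dimension)`` float array, one row per key.
    case_policy:
        "lowercase" if the release case-folded its corpus, else "mixed".
    phrase_policy:
        "multiword_keys" if the vocabulary contains joined phrases
        (1-3 grams), "unigram_only" otherwise.
    """

    name: str
    vocabulary: list[str]
    vectors: np.ndarray
    unit: Literal["token", "character"] = "token"
    case_policy: Literal["lowercase", "mixed"] = "lowercase"
    phrase_policy: Literal["unigram_only", "multiword_keys"] = "unigram_only"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            self.vectors = self.vectors.reshape(len(self.vocabulary), -1)
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError(
                f"source {self.name!r}: {len(self.vocabulary)} keys but "
                f"{self.vectors.shape[0]} vectors"
            )
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError(f"source {self.name!r}: duplicate vocabulary keys")
        if self.vectors.size and not np.all(np.isfinite(self.vectors)):
            raise ValueError(f"source {self.name!r}: non-finite vector components")
        self._index: dict[str, int] = {k: i for i, k in enumerate(self.vocabulary)}

    @property
    def dimension(self) -> int:
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def vector(self, key: str) -> np.ndarray:
        try:
            return self.vectors[self._index[key]]
        except KeyError:
            raise KeyError(f"key {key!r} not in source {self.name!r}") from None

    def index_of(self, key: str) -> int:
        return self._index[key]


@dataclass(frozen=True)
class QueryTerm:
    """A seed term to probe against the sources.

    ``category`` reflects the seed-list assignment (symptom, finding or
    disorder); ``has_modifier`` marks phrases carrying a qualifier or
    anatomical modifier ("dry cough" vs "cough").
    """

    surface: str
    category: Literal["symptom", "finding", "disorder"] = "symptom"
    has_modifier: bool = False

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise ValueError("query surface must be non-empty")


# ---------------------------------------------------------------------------
# file dialects


def _parse_text_rows(
    lines: Iterable[tuple[int, str]], path: Path, expected_dim: int | None
) -> tuple[list[str], list[np.ndarray]]:
    vocab: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    dim = expected_dim
    for lineno, line in lines:
        parts = line.rstrip("\n").split(" ")
        # trailing spaces in some released files produce an empty last field
        if parts and parts[-1] == "":
            parts = parts[:-1]
        if not parts or (len(parts) == 1 and parts[0] == ""):
            continue
        key, fields = parts[0], parts[1:]
        if dim is None:
            dim = len(fields)
        if len(fields) != dim:
            raise ValueError(
                f"{path}:{lineno}: row for {key!r} has {len(fields)} "
                f"components, expected {dim}"
            )
        try:
            vec = np.array([float(x) for x in fields], dtype=np.float64)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if key in seen:
            logger.warning("%s:%d: duplicate key %r; first occurrence wins", path, lineno, key)
            continue
        seen.add(key)
        vocab.append(key)
        rows.append(vec)
    return vocab, rows


def read_embedding(
    path: str | Path,
    dialect: Dialect,
    *,
    name: str | None = None,
    unit: Literal["token", "character"] = "token",
    case_policy: Literal["lowercase", "mixed"] = "lowercase",
    phrase_policy: Literal["unigram_only", "multiword_keys"] = "unigram_only",
    metadata: dict | None = None,
) -> EmbeddingSource:
    """Load an embedding file in the named dialect.

    Headered dialects (word2vec_text, fasttext_vec, word2vec_binary) must
    declare a row count matching the body; glove_text infers the dimension
    from its first row. Files are decoded as UTF-8 with replacement on
    errors (public releases are inconsistently encoded). Duplicate keys
    keep the first occurrence with a logged warning.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}; expected one of {DIALECTS}")
    name = name or path.stem

    if dialect == "word2vec_binary":
        vocab, vectors = _read_word2vec_binary(path)
    else:
        with open(path, encoding="utf-8", errors="replace") as fh:
            lines = enumerate(fh, start=1)
            declared = None
            dim = None
            if dialect in ("word2vec_text", "fasttext_vec"):
                try:
                    _, header = next(lines)
                except StopIteration:
                    raise ValueError(f"{path}:1: empty file, expected 'count dim' header")
                try:
                    declared, dim = (int(x) for x in header.split())
                except ValueError:
                    raise ValueError(
                        f"{path}:1: malformed header {header.strip()!r}, expected 'count dim'"
                    ) from None
            vocab, rows = _parse_text_rows(lines, path, dim)
            if declared is not None and len(rows) != declared:
                raise ValueError(
                    f"{path}: header declares {declared} rows but file has "
                    f"{len(rows)} (last parsed line {len(rows) + 1})"
                )
            vectors = np.array(rows) if rows else np.empty((0, dim or 0))

    return EmbeddingSource(
        name=name,
        vocabulary=vocab,
        vectors=vectors,
        unit=unit,
        case_policy=case_policy,
        phrase_policy=phrase_policy,
        metadata=metadata or {},
    )


def _read_word2vec_binary(path: Path) -> tuple[list[str], np.ndarray]:
    with open(path, "rb") as fh:
        header = fh.readline().decode("utf-8", errors="replace")
        try:
            count, dim = (int(x) for x in header.split())
        except ValueError:
            raise ValueError(f"{path}:1: malformed binary header {header.strip()!r}") from None
        vocab: list[str] = []
        vectors = np.empty((count, dim), dtype=np.float64)
        width = struct.calcsize(f"<{dim}f")
        for i in range(count):
            key_bytes = bytearray()
            while True:
                ch = fh.read(1)
                if not ch:
                    raise ValueError(f"{path}: truncated at entry {i + 1} of {count}")
                if ch == b" ":
                    break
                if ch != b"\n":  # tolerate leading newlines between records
                    key_bytes.extend(ch)
            buf = fh.read(width)
            if len(buf) != width:
                raise ValueError(f"{path}: truncated vector at entry {i + 1} of {count}")
            vocab.append(key_bytes.decode("utf-8", errors="replace"))
            vectors[i] = np.frombuffer(buf, dtype="<f4")
    if len(set(vocab)) != len(vocab):
        keep: dict[str, int] = {}
        for i, k in enumerate(vocab):
            if k not in keep:
                keep[k] = i
            else:
                logger.warning("%s: duplicate key %r; first occurrence wins", path, k)
        idx = sorted(keep.values())
        vocab = [vocab[i] for i in idx]
        vectors = vectors[idx]
    return vocab, vectors


def write_embedding(source: EmbeddingSource, path: str | Path, dialect: Dialect) -> Path:
    """Serialize a source so that :func:`read_embedding` recovers it.

    Text dialects print components with ``repr``-faithful ``%.8g``
    formatting (round-trip error below 1e-6 per component); the binary
    dialect stores float32.
    """
    path = Path(path)
    if dialect == "word2vec_binary":
        with open(path, "wb") as fh:
            fh.write(f"{len(source)} {source.dimension}\n".encode())
            for key, vec in zip(source.vocabulary, source.vectors):
                fh.write(key.encode("utf-8") + b" ")
                fh.write(np.asarray(vec, dtype="<f4").tobytes())
        return path
    if dialect not in DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w", encoding="utf-8") as fh:
        if dialect in ("word2vec_text", "fasttext_vec"):
            fh.write(f"{len(source)} {source.dimension}\n")
        for key, vec in zip(source.vocabulary, source.vectors):
            fh.write(key + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")
    return path


# ---------------------------------------------------------------------------
# query normalization


def normalize_query(term: str, source: EmbeddingSource) -> list[str]:
    """Return, in priority order, the vocabulary keys under which ``term``
    should be probed in ``source``.

    The term is case-folded if the source was built lowercase, then
    multi-word phrases are tried underscore-joined, hyphen-joined, and
    verbatim (underscore is the dominant phrase-key convention in public
    releases). Only forms present in the vocabulary are returned; an empty
    list means out-of-vocabulary.
    """
    if not term.strip():
        raise ValueError("query term must be non-empty")
    surface = term.strip()
    if source.case_policy == "lowercase":
        surface = surface.lower()
    tokens = surface.split()
    candidates: list[str] = []
    if len(tokens) > 1:
        candidates.extend(["_".join(tokens), "-".join(tokens), surface])
    else:
        candidates.append(surface)
    out: list[str] = []
    for cand in candidates:
        if cand in source and cand not in out:
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# source registry


@dataclass(frozen=True)
class RegistryEntry:
    """One row of a source-registry config: where a source lives and how
    it was built (name, dialect, path, unit, case/phrase policy, optional
    per-source phrase delimiter override)."""

    name: str
    path: str
    dialect: Dialect
    unit: Literal["token", "character"] = "token"
    case_policy: Literal["lowercase", "mixed"] = "lowercase"
    phrase_policy: Literal["unigram_only", "multiword_keys"] = "unigram_only"
    metadata: dict = field(default_factory=dict)


def load_registry(path: str | Path) -> list[RegistryEntry]:
    """Parse a YAML/JSON source registry into entries.

    Expected top-level key ``sources``: a list of mappings with at least
    ``name``, ``path`` and ``dialect``.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = []
    for row in doc["sources"]:
        entries.append(
            RegistryEntry(
                name=row["name"],
                path=row["path"],
                dialect=row["dialect"],
                unit=row.get("unit", "token"),
                case_policy=row.get("case_policy", "lowercase"),
                phrase_policy=row.get("phrase_policy", "unigram_only"),
                metadata=row.get("metadata", {}),
            )
        )
    return entries


def load_sources(entries: Sequence[RegistryEntry], base_dir: str | Path = ".") -> list[EmbeddingSource]:
    base = Path(base_dir)
    return [
        read_embedding(
            base / e.path,
            e.dialect,
            name=e.name,
            unit=e.unit,
            case_policy=e.case_policy,
            phrase_policy=e.phrase_policy,
            metadata=e.metadata,
        )
        for e in entries
    ]
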