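"""The ten-class semantic annotation scheme for query/returned term pairs.

Each returned candidate term is labeled, relative to its query term, with
one of ten closed semantic classes. The display color associated with each
class is carried along because downstream visual exports key on it.
"""

from __future__ import annotations

import enum


class SemanticType(enum.Enum):
    """Semantic class of a returned term relative to its query term.

    The label set is closed: exactly these ten members, each with a fixed
    display color. Examples of the intent of each class:

    - ``NEGATION``: expresses absence of the queried concept ("afebrile"
      for "fever").
    - ``SYNONYM``: a lexical variant with the same meaning, including
      misspellings and short forms ("pyrexia" for "fever").
    - ``SYMPTOM_SIGN``: a symptom, observation, finding or syndrome that is
      not a synonym of the query ("fever" returned for "cough").
    - ``DISEASE_DISORDER``: a disease/disorder/diagnosis that is not a
      synonym ("pneumonia" returned for "dyspnea").
    - ``HYPONYM``: a more specific term ("ground-glass opacities" for
      "opacities").
    - ``HYPERNYM``: a broader term ("cough" for "productive cough").
    - ``QUALIFIER``: a non-clinical temporal/spatial/quality/extent/size
      descriptor ("dry" for "cough").
    - ``ANATOMICAL_LOCATION``: an anatomical or positional descriptor
      ("lower lobe").
    - ``THERAPEUTIC``: a medication, therapy, or procedure ("mechanical
      ventilation").
    - ``OTHER``: anything else, including non-clinical senses ("traffic"
      returned for "congestion").
    """

    NEGATION = "negation"
    SYNONYM = "synonym"
    SYMPTOM_SIGN = "symptom_sign"
    DISEASE_DISORDER = "disease_disorder"
    HYPONYM = "hyponym"
    HYPERNYM = "hypernym"
    QUALIFIER = "qualifier"
    ANATOMICAL_LOCATION = "anatomical_location"
    THERAPEUTIC = "therapeutic"
    OTHER = "other"

    @property
    def color(self) -> str:
        return _COLORS[self]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


_COLORS: dict[SemanticType, str] = {
    SemanticType.NEGATION: "black",
    SemanticType.SYNONYM: "green",
    SemanticType.SYMPTOM_SIGN: "yellow",
    SemanticType.DISEASE_DISORDER: "blue",
    SemanticType.HYPONYM: "light red",
    SemanticType.HYPERNYM: "dark red",
    SemanticType.QUALIFIER: "teal",
    SemanticType.ANATOMICAL_LOCATION: "orange",
    SemanticType.THERAPEUTIC: "purple",
    SemanticType.OTHER: "grey",
}

#: Canonical ordering used for matrices and tabular exports.
LABEL_ORDER: tuple[SemanticType, ...] = tuple(SemanticType)

#: Fixed tie-break priority for consensus labeling (highest first).
CONSENSUS_PRIORITY: tuple[SemanticType, ...] = (
    SemanticType.SYNONYM,
    SemanticType.NEGATION,
    SemanticType.HYPERNYM,
    SemanticType.HYPONYM,
    SemanticType.SYMPTOM_SIGN,
    SemanticType.DISEASE_DISORDER,
    SemanticType.QUALIFIER,
    SemanticType.ANATOMICAL_LOCATION,
    SemanticType.THERAPEUTIC,
    SemanticType.OTHER,
)


def parse_label(value: str | SemanticType) -> SemanticType:
    """Coerce a string (case-insensitive) or enum member to a SemanticType."""
    if isinstance(value, SemanticType):
        return value
    try:
        return SemanticType(value.strip().lower())
    except ValueError:
        raise ValueError(
            f"unknown semantic type {value!r}; expected one of "
            f"{[m.value for m in SemanticType]}"
        ) from None
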