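"""Cross-source term-identity normalization.

The same concept surfaces as "dry_cough", "dry-cough" or "dry cough"
depending on the phrase-key convention of the corpus that produced it.
For cross-source aggregation and lexicon storage, terms are case-folded
and the three delimiters collapsed to a single canonical space.
"""

from __future__ import annotations

import re

_DELIMS = re.compile(r"[\s_\-]+")


def canonical_term(term: str) -> str:
    """Case-folded, delimiter-normalized form: underscore = hyphen = space."""
    return _DELIMS.sub(" ", term.strip().casefold()).strip()
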