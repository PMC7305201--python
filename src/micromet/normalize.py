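"""Shared text normalization.

Every component that compares free text to a vocabulary (classification,
entity extraction, gold-standard joining, chemical-name mapping) must use the
same normalization, otherwise a name can match in one stage and silently miss
in another. The rule is deliberately simple: lowercase, map every
non-alphanumeric character (hyphens included) to a space, collapse runs of
whitespace. Non-ASCII letters are lowercased but never transliterated.
"""

from __future__ import annotations

import re

__all__ = ["normalize_text", "tokenize"]

# \w is unicode-aware; underscore is carved back out so it behaves like
# punctuation rather than a word character.
_NON_WORD = re.compile(r"[\W_]+", re.UNICODE)


def normalize_text(text: str) -> str:
    """Return the canonical matchable form of ``text``.

    Idempotent: ``normalize_text(normalize_text(t)) == normalize_text(t)``.
    """
    return _NON_WORD.sub(" ", text.lower()).strip()


def tokenize(text: str) -> list[str]:
    """Split text into normalized tokens (normalizes first)."""
    norm = normalize_text(text)
    return norm.split(" ") if norm else []
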