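"""Two-stage keyword classification of a corpus.

Stage one keeps records mentioning microbes/microbiota; stage two narrows the
microbial subset to metabolism-related records. Matching emulates a PubMed
keyword search over the record's matchable text: by default a keyword matches
any token that *starts with* it (so "metabolite" catches "metabolites"), but
the prefix is anchored at token start, so "antimicrobial" does not match
"microbial". Exact-token matching is available as a stricter mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .medline_io import FIELDS, Corpus, MedlineRecord, record_text

__all__ = [
    "MICROBIAL_KEYWORDS",
    "METABOLISM_KEYWORDS",
    "MATCH_MODES",
    "KeywordSet",
    "preset_keywords",
    "matches",
    "classify_corpus",
]

logger = logging.getLogger(__name__)

# Preset stage vocabularies (deduplicated).
MICROBIAL_KEYWORDS: frozenset[str] = frozenset(
    {"microbial", "microbiome", "microbiota", "microflora"}
)
METABOLISM_KEYWORDS: frozenset[str] = frozenset(
    {"metabolism", "metabolite", "metabolic", "metabolome"}
)

MATCH_MODES = ("exact-token", "token-prefix")


@dataclass(frozen=True)
class KeywordSet:
    """A named set of lowercase single-token keywords plus a match mode."""

    name: str
    keywords: frozenset[str]
    match_mode: str = "token-prefix"

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("KeywordSet requires at least one keyword")
        for kw in self.keywords:
            if kw != kw.lower() or any(ch.isspace() for ch in kw):
                raise ValueError(
                    f"keyword {kw!r} must be lowercase with no internal whitespace"
                )
        if self.match_mode not in MATCH_MODES:
            raise ValueError(
                f"match_mode must be one of {MATCH_MODES}, got {self.match_mode!r}"
            )


def preset_keywords(stage: str, match_mode: str = "token-prefix") -> KeywordSet:
    """Return the preset keyword set for ``stage`` ('microbial' or 'metabolism')."""
    if stage == "microbial":
        return KeywordSet("microbial", MICROBIAL_KEYWORDS, match_mode)
    if stage == "metabolism":
        return KeywordSet("metabolism", METABOLISM_KEYWORDS, match_mode)
    raise ValueError(f"unknown classification stage: {stage!r}")


def matches(
    record: MedlineRecord, ks: KeywordSet, fields: Iterable[str] = FIELDS
) -> bool:
    """True iff any token of the record's matchable text matches ``ks``."""
    text = record_text(record, fields)
    if not text:
        return False
    tokens = text.split(" ")
    if ks.match_mode == "exact-token":
        return any(tok in ks.keywords for tok in tokens)
    return any(tok.startswith(kw) for tok in tokens for kw in ks.keywords)


def classify_corpus(
    corpus: Corpus, ks: KeywordSet, fields: Iterable[str] = FIELDS
) -> Corpus:
    """Order-preserving subset of ``corpus`` matching ``ks``."""
    fields = tuple(fields)
    kept = [rec for rec in corpus if matches(rec, ks, fields)]
    logger.info(
        "classify[%s]: %d of %d records kept", ks.name, len(kept), len(corpus)
    )
    label = f"{corpus.source_label}|{ks.name}" if corpus.source_label else ks.name
    return Corpus(records=kept, source_label=label)
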