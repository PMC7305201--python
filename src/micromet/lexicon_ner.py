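"""Metabolite lexicon, dictionary-based concept extraction, and document
frequencies.

A lexicon maps normalized synonym strings to the concepts they name
(many-to-many). Extraction scans a record's normalized token stream and
resolves overlapping candidate matches leftmost-longest, so a nested shorter
synonym ("trimethylamine") never fires inside a longer one
("trimethylamine n oxide") at the same position, while separate occurrences
elsewhere in the document still count. Counting is per document: a concept
contributes at most 1 to a document-frequency cell no matter how often it is
mentioned.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .medline_io import FIELDS, Corpus, MedlineRecord, record_text
from .normalize import normalize_text, tokenize

__all__ = [
    "Lexicon",
    "LexiconStats",
    "DocumentFrequencyRecord",
    "DocumentFrequencyTable",
    "build_lexicon",
    "read_lexicon_tsv",
    "write_lexicon_tsv",
    "extract_concepts",
    "compute_df",
    "read_df_tsv",
    "write_df_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LexiconStats:
    n_concepts: int
    n_synonyms: int  # distinct normalized synonym strings
    n_mappings: int  # synonym -> concept pairs


class Lexicon:
    """Synonym → concept index with a token-sequence matcher.

    Built via :func:`build_lexicon`; direct construction takes a mapping of
    concept id → preferred name and an index of normalized synonym →
    set of concept ids.
    """

    def __init__(
        self,
        concepts: dict[str, str],
        synonym_index: dict[str, frozenset[str]],
    ) -> None:
        self.concepts = dict(concepts)
        self.synonym_index = dict(synonym_index)
        # Matcher structure: first token -> [(token tuple, concept ids)],
        # longest sequences first so the scanner can take the first hit.
        by_first: dict[str, list[tuple[tuple[str, ...], frozenset[str]]]] = {}
        for syn, ids in self.synonym_index.items():
            toks = tuple(syn.split(" "))
            by_first.setdefault(toks[0], []).append((toks, ids))
        for entries in by_first.values():
            entries.sort(key=lambda item: (-len(item[0]), item[0]))
        self._by_first_token = by_first
        self._max_len = max((len(s.split(" ")) for s in synonym_index), default=0)

    def __len__(self) -> int:
        return len(self.concepts)

    def preferred_name(self, concept_id: str) -> str:
        return self.concepts[concept_id]

    @property
    def stats(self) -> LexiconStats:
        return LexiconStats(
            n_concepts=len(self.concepts),
            n_synonyms=len(self.synonym_index),
            n_mappings=sum(len(ids) for ids in self.synonym_index.values()),
        )

    def ambiguous_synonyms(self) -> dict[str, frozenset[str]]:
        """Synonyms that name more than one concept (for curation review)."""
        return {s: ids for s, ids in self.synonym_index.items() if len(ids) > 1}

    def match_tokens(self, tokens: Sequence[str]) -> set[str]:
        """Concept ids matched in a token sequence, leftmost-longest."""
        found: set[str] = set()
        i = 0
        n = len(tokens)
        while i < n:
            entries = self._by_first_token.get(tokens[i])
            matched_len = 0
            if entries:
                for toks, ids in entries:
                    k = len(toks)
                    if i + k <= n and tuple(tokens[i : i + k]) == toks:
                        found.update(ids)
                        matched_len = k
                        break  # entries are longest-first
            i += matched_len if matched_len else 1
        return found


def build_lexicon(
    entries: Iterable[tuple[str, str, str]],
    min_synonym_chars: int = 2,
    exclude_numeric: bool = True,
) -> Lexicon:
    """Build a :class:`Lexicon` from (concept id, preferred name, synonym) rows.

    Preferred names are self-registered as synonyms of their own concept.
    Synonyms that normalize to the empty string, fall under
    ``min_synonym_chars``, or are purely numeric (when ``exclude_numeric``)
    are skipped with a warning — lexicon hygiene, not an error.
    """
    concepts: dict[str, str] = {}
    index: dict[str, set[str]] = {}
    skipped: list[str] = []

    def register(norm_syn: str, concept_id: str) -> None:
        if not norm_syn or len(norm_syn) < min_synonym_chars:
            skipped.append(norm_syn)
            return
        if exclude_numeric and norm_syn.replace(" ", "").isdigit():
            skipped.append(norm_syn)
            return
        index.setdefault(norm_syn, set()).add(concept_id)

    for concept_id, preferred, synonym in entries:
        if not concept_id:
            raise ValueError("concept id must be non-empty")
        if concept_id in concepts and concepts[concept_id] != preferred:
            raise ValueError(
                f"conflicting preferred names for concept {concept_id}: "
                f"{concepts[concept_id]!r} vs {preferred!r}"
            )
        concepts[concept_id] = preferred
        register(normalize_text(preferred), concept_id)
        register(normalize_text(synonym), concept_id)

    if skipped:
        logger.warning(
            "build_lexicon: skipped %d synonym(s) failing hygiene rules", len(skipped)
        )
    lex = Lexicon(concepts, {s: frozenset(ids) for s, ids in index.items()})
    stats = lex.stats
    logger.info(
        "lexicon built: %d concepts, %d synonyms, %d synonym->concept mappings",
        stats.n_concepts,
        stats.n_synonyms,
        stats.n_mappings,
    )
    ambiguous = lex.ambiguous_synonyms()
    if ambiguous:
        logger.info("lexicon has %d ambiguous synonym(s)", len(ambiguous))
    return lex


def read_lexicon_tsv(path: str | Path, **kwargs) -> Lexicon:
    """Read a lexicon TSV with header ``concept_id  preferred_name  synonym``."""
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"concept_id", "preferred_name", "synonym"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns {sorted(required)}")
        for row in reader:
            rows.append((row["concept_id"], row["preferred_name"], row["synonym"]))
    return build_lexicon(rows, **kwargs)


def write_lexicon_tsv(
    entries: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["concept_id", "preferred_name", "synonym"])
        for row in entries:
            writer.writerow(row)


def extract_concepts(
    record: MedlineRecord, lexicon: Lexicon, fields: Iterable[str] = FIELDS
) -> frozenset[str]:
    """Document-level set of concept ids recognized in ``record``.

    Ambiguous synonyms contribute all their concepts; duplicates collapse.
    """
    tokens = tokenize(record_text(record, fields))
    return frozenset(lexicon.match_tokens(tokens))


# ---------------------------------------------------------------------------
# Document frequencies
# ---------------------------------------------------------------------------


@dataclass
class DocumentFrequencyRecord:
    concept_id: str
    preferred_name: str
    df: int  # documents in the full corpus containing the concept
    dfc: int  # documents in the classified subset containing the concept

    def __post_init__(self) -> None:
        if not (0 <= self.dfc <= self.df):
            raise ValueError(
                f"{self.concept_id}: require 0 <= dfc <= df, got dfc={self.dfc}, df={self.df}"
            )


@dataclass
class DocumentFrequencyTable:
    records: dict[str, DocumentFrequencyRecord]
    n_all: int
    n_classified: int

    def __post_init__(self) -> None:
        if self.n_classified > self.n_all:
            raise ValueError("n_classified cannot exceed n_all")
        for rec in self.records.values():
            if rec.df > self.n_all or rec.dfc > self.n_classified:
                raise ValueError(
                    f"{rec.concept_id}: counts exceed corpus sizes "
                    f"(df={rec.df}/{self.n_all}, dfc={rec.dfc}/{self.n_classified})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())


def compute_df(
    corpus_all: Corpus,
    corpus_classified: Corpus,
    lexicon: Lexicon,
    fields: Iterable[str] = FIELDS,
) -> DocumentFrequencyTable:
    """Per-concept document frequencies in the full corpus and the subset.

    Only concepts seen at least once in ``corpus_all`` appear in the table.
    """
    fields = tuple(fields)
    all_pmids = set(corpus_all.pmids())
    for pmid in corpus_classified.pmids():
        if pmid not in all_pmids:
            raise ValueError(f"classified PMID {pmid} is not in the full corpus")
    classified = set(corpus_classified.pmids())

    df: dict[str, int] = {}
    dfc: dict[str, int] = {}
    for rec in corpus_all:
        concepts = extract_concepts(rec, lexicon, fields)
        in_subset = rec.pmid in classified
        for cid in concepts:
            df[cid] = df.get(cid, 0) + 1
            if in_subset:
                dfc[cid] = dfc.get(cid, 0) + 1

    records = {
        cid: DocumentFrequencyRecord(
            concept_id=cid,
            preferred_name=lexicon.preferred_name(cid),
            df=count,
            dfc=dfc.get(cid, 0),
        )
        for cid, count in df.items()
    }
    return DocumentFrequencyTable(
        records=records, n_all=len(corpus_all), n_classified=len(corpus_classified)
    )


def write_df_tsv(table: DocumentFrequencyTable, path: str | Path) -> None:
    """Write ``concept_id  preferred_name  df  dfc`` rows (corpus sizes in a comment)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        handle.write(f"# n_all={table.n_all}\tn_classified={table.n_classified}\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["concept_id", "preferred_name", "df", "dfc"])
        for rec in sorted(table.records.values(), key=lambda r: r.concept_id):
            writer.writerow([rec.concept_id, rec.preferred_name, rec.df, rec.dfc])


def read_df_tsv(path: str | Path) -> DocumentFrequencyTable:
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as handle:
        first = handle.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing corpus-size comment line")
        meta = dict(part.split("=") for part in first[1:].strip().split("\t"))
        reader = csv.DictReader(handle, delimiter="\t")
        records = {}
        for row in reader:
            records[row["concept_id"]] = DocumentFrequencyRecord(
                concept_id=row["concept_id"],
                preferred_name=row["preferred_name"],
                df=int(row["df"]),
                dfc=int(row["dfc"]),
            )
    return DocumentFrequencyTable(
        records=records,
        n_all=int(meta["n_all"]),
        n_classified=int(meta["n_classified"]),
    )
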