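"""Reading, writing and text assembly for bibliographic records.

Supports two on-disk representations:

* the standard MEDLINE/PubMed tagged text export (``PMID- ``, ``TI  - `` ...,
  continuation lines indented), read and written losslessly for the five
  fields this package uses;
* a JSON-lines canonical format (one object per record) whose write/read
  round-trip is the identity.

The five content fields — title, abstract, MeSH headings, keywords,
chemicals — are the matchable surface of a record for both classification
and entity extraction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .normalize import normalize_text

__all__ = [
    "FIELDS",
    "MedlineRecord",
    "Corpus",
    "read_medline_tagged",
    "write_medline_tagged",
    "read_jsonl",
    "write_jsonl",
    "record_text",
]

#: Canonical order of the five matchable fields.
FIELDS: tuple[str, ...] = ("title", "abstract", "mesh_headings", "keywords", "chemicals")

_LIST_FIELDS = frozenset({"mesh_headings", "keywords", "chemicals"})


@dataclass
class MedlineRecord:
    """One bibliographic record.

    Any of the five content fields may be empty; only the PMID is mandatory.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_headings: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    chemicals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("MedlineRecord requires a non-empty pmid")


@dataclass
class Corpus:
    """An ordered collection of records with unique PMIDs."""

    records: list[MedlineRecord] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.pmid in seen:
                raise ValueError(f"duplicate PMID in corpus: {rec.pmid}")
            seen.add(rec.pmid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MedlineRecord]:
        return iter(self.records)

    def pmids(self) -> list[str]:
        return [rec.pmid for rec in self.records]


def record_text(record: MedlineRecord, fields: Iterable[str] = FIELDS) -> str:
    """Assemble the normalized matchable text of ``record``.

    ``fields`` selects a non-empty subset of the five field names; selected
    fields are joined in canonical order with single spaces and normalized
    (lowercase, punctuation to spaces, whitespace collapsed).
    """
    selected = set(fields)
    if not selected:
        raise ValueError("fields must be a non-empty subset of the five field names")
    unknown = selected - set(FIELDS)
    if unknown:
        raise ValueError(f"unknown field name(s): {sorted(unknown)}")
    parts: list[str] = []
    for name in FIELDS:
        if name not in selected:
            continue
        value = getattr(record, name)
        if name in _LIST_FIELDS:
            parts.extend(value)
        elif value:
            parts.append(value)
    return normalize_text(" ".join(parts))


# ---------------------------------------------------------------------------
# MEDLINE tagged format
# ---------------------------------------------------------------------------

# A new field line: up to-4-char tag, optional padding, "- ", value.
_TAG_LINE = re.compile(r"^([A-Z][A-Z0-9]{0,3}) {0,3}- (.*)$")

_TAG_TO_FIELD = {
    "TI": "title",
    "AB": "abstract",
    "MH": "mesh_headings",
    "OT": "keywords",
    "RN": "chemicals",
    "NM": "chemicals",
}


def read_medline_tagged(path: str | Path) -> Corpus:
    """Parse a MEDLINE tagged export into a :class:`Corpus`.

    One record per PMID block; unknown tags are ignored; continuation lines
    (indented) extend the previous tag's value. A block without a PMID or a
    duplicated PMID is a hard error.
    """
    path = Path(path)
    records: list[MedlineRecord] = []
    seen: set[str] = set()

    block: list[tuple[str, str]] = []  # (tag, value) pairs, continuations merged
    block_start = 0

    def flush(end_line: int) -> None:
        if not block:
            return
        pmid = ""
        fields: dict[str, object] = {
            "title": "",
            "abstract": "",
            "mesh_headings": [],
            "keywords": [],
            "chemicals": [],
        }
        for tag, value in block:
            if tag == "PMID":
                pmid = value.strip()
            elif tag in _TAG_TO_FIELD:
                name = _TAG_TO_FIELD[tag]
                if name in _LIST_FIELDS:
                    fields[name].append(value)  # type: ignore[union-attr]
                else:
                    existing = fields[name]
                    fields[name] = f"{existing} {value}" if existing else value
        if not pmid:
            raise ValueError(
                f"{path}: record block starting at line {block_start} has no PMID"
            )
        if pmid in seen:
            raise ValueError(f"{path}: duplicate PMID {pmid}")
        seen.add(pmid)
        records.append(MedlineRecord(pmid=pmid, **fields))  # type: ignore[arg-type]
        block.clear()

    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            match = _TAG_LINE.match(line)
            if match:
                if not block:
                    block_start = lineno
                block.append((match.group(1), match.group(2)))
            elif line.startswith(" "):
                if not block:
                    raise ValueError(
                        f"{path}: line {lineno}: continuation line outside a record block"
                    )
                tag, value = block[-1]
                block[-1] = (tag, f"{value} {line.strip()}")
            else:
                raise ValueError(f"{path}: line {lineno}: malformed line: {line!r}")
        flush(lineno if records or block else 0)
    return Corpus(records=records, source_label=str(path))


def write_medline_tagged(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus in MEDLINE tagged format (no line wrapping)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for rec in corpus:
            lines = [f"PMID- {rec.pmid}"]
            if rec.title:
                lines.append(f"TI  - {rec.title}")
            if rec.abstract:
                lines.append(f"AB  - {rec.abstract}")
            lines.extend(f"MH  - {term}" for term in rec.mesh_headings)
            lines.extend(f"OT  - {term}" for term in rec.keywords)
            lines.extend(f"NM  - {term}" for term in rec.chemicals)
            handle.write("\n".join(lines) + "\n\n")


# ---------------------------------------------------------------------------
# JSON-lines canonical format
# ---------------------------------------------------------------------------


def read_jsonl(path: str | Path) -> Corpus:
    """Read the canonical JSON-lines corpus format."""
    path = Path(path)
    records: list[MedlineRecord] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip():
                continue
            obj = json.loads(raw)
            if "pmid" not in obj or not obj["pmid"]:
                raise ValueError(f"{path}: line {lineno}: record has no pmid")
            records.append(
                MedlineRecord(
                    pmid=str(obj["pmid"]),
                    title=obj.get("title", ""),
                    abstract=obj.get("abstract", ""),
                    mesh_headings=list(obj.get("mesh_headings", [])),
                    keywords=list(obj.get("keywords", [])),
                    chemicals=list(obj.get("chemicals", [])),
                )
            )
    return Corpus(records=records, source_label=str(path))


def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Write the canonical JSON-lines corpus format (lossless round-trip)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for rec in corpus:
            handle.write(
                json.dumps(
                    {
                        "pmid": rec.pmid,
                        "title": rec.title,
                        "abstract": rec.abstract,
                        "mesh_headings": rec.mesh_headings,
                        "keywords": rec.keywords,
                        "chemicals": rec.chemicals,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def subset_corpus(corpus: Corpus, pmids: Sequence[str] | set[str], label: str = "") -> Corpus:
    """Order-preserving subset of a corpus by PMID membership."""
    wanted = set(pmids)
    return Corpus(
        records=[rec for rec in corpus if rec.pmid in wanted],
        source_label=label or corpus.source_label,
    )
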