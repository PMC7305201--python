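"""Mapping prioritized metabolites to chemical–gene associations and scoring
genes by the number of associated metabolites.

Joining is name-based: a metabolite maps to a table chemical when its
normalized preferred name, any lexicon synonym, or a user-supplied alias
equals the chemical's normalized name (mirroring e.g. "butyric acid" in a
metabolite vocabulary joining to "butyrate" in an association table).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from .lexicon_ner import Lexicon
from .normalize import normalize_text

__all__ = [
    "ChemicalGeneTable",
    "GeneScore",
    "MetaboliteMapping",
    "load_chem_gene",
    "load_aliases",
    "map_metabolites",
    "score_genes",
    "write_gene_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class ChemicalGeneTable:
    """Normalized chemical name → set of associated gene symbols."""

    associations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chem, genes in self.associations.items():
            if not genes:
                raise ValueError(f"chemical {chem!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.associations)

    def genes_for(self, chemical: str) -> set[str]:
        return self.associations.get(normalize_text(chemical), set())


def load_chem_gene(
    path: str | Path, min_score: float | None = None
) -> ChemicalGeneTable:
    """Read a ``chemical<TAB>gene[<TAB>score]`` table.

    Chemical names are normalized; duplicate pairs collapse. When
    ``min_score`` is given, rows whose third column is below it are dropped
    (rows without a score column then error).
    """
    path = Path(path)
    associations: dict[str, set[str]] = {}
    with path.open(encoding="utf-8", newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("chemical\t"):
                continue  # optional header
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected 'chemical<TAB>gene[<TAB>score]'"
                )
            if min_score is not None:
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}: line {lineno}: min_score given but row has no score column"
                    )
                if float(parts[2]) < min_score:
                    continue
            chem = normalize_text(parts[0])
            associations.setdefault(chem, set()).add(parts[1].strip())
    return ChemicalGeneTable(associations=associations)


def load_aliases(path: str | Path) -> dict[str, str]:
    """Read a ``metabolite_name<TAB>chemical_name`` alias table (normalized)."""
    path = Path(path)
    aliases: dict[str, str] = {}
    with path.open(encoding="utf-8", newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'metabolite_name<TAB>chemical_name'"
                )
            aliases[normalize_text(parts[0])] = normalize_text(parts[1])
    return aliases


class MetaboliteMapping(NamedTuple):
    """Result of joining metabolites to a chemical–gene table."""

    mapped: dict[str, str]  # metabolite name (as given) -> matched chemical key
    unmapped: list[str]


def map_metabolites(
    metabolites: Iterable[str],
    table: ChemicalGeneTable,
    lexicon: Lexicon | None = None,
    aliases: Mapping[str, str] | None = None,
) -> MetaboliteMapping:
    """Join metabolite names to table chemicals by normalized name.

    A metabolite maps if its normalized name, any synonym the lexicon lists
    for its concept, or an alias-table entry equals a table chemical key.
    Unmapped metabolites are reported, not dropped silently.
    """
    aliases = dict(aliases or {})
    # concept id -> normalized synonyms, resolvable from a metabolite's name
    name_to_concepts: dict[str, set[str]] = {}
    concept_synonyms: dict[str, set[str]] = {}
    if lexicon is not None:
        for syn, ids in lexicon.synonym_index.items():
            for cid in ids:
                concept_synonyms.setdefault(cid, set()).add(syn)
        for cid, preferred in lexicon.concepts.items():
            name_to_concepts.setdefault(normalize_text(preferred), set()).add(cid)

    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for metabolite in metabolites:
        norm = normalize_text(metabolite)
        candidates = [norm]
        if norm in aliases:
            candidates.append(aliases[norm])
        for cid in name_to_concepts.get(norm, ()):
            candidates.extend(sorted(concept_synonyms.get(cid, ())))
        hit = next((c for c in candidates if c in table.associations), None)
        if hit is None:
            unmapped.append(metabolite)
        else:
            mapped[metabolite] = hit
    if unmapped:
        logger.info(
            "map_metabolites: %d of %d metabolite(s) unmapped",
            len(unmapped), len(mapped) + len(unmapped),
        )
    return MetaboliteMapping(mapped=mapped, unmapped=unmapped)


class GeneScore(NamedTuple):
    gene: str
    score: int  # distinct mapped metabolites associated with the gene


def score_genes(
    mapping: MetaboliteMapping, table: ChemicalGeneTable
) -> list[GeneScore]:
    """Count, per gene, the distinct mapped metabolites that list it.

    Sorted by score descending, ties by gene symbol ascending. Two
    metabolites mapping to the same chemical each count once.
    """
    counts: dict[str, int] = {}
    for _metabolite, chem in mapping.mapped.items():
        for gene in table.associations.get(chem, ()):
            counts[gene] = counts.get(gene, 0) + 1
    scores = [GeneScore(gene=g, score=c) for g, c in counts.items()]
    scores.sort(key=lambda gs: (-gs.score, gs.gene))
    return scores


def write_gene_scores(scores: list[GeneScore], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "score"])
        for gs in scores:
            writer.writerow([gs.gene, gs.score])
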