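"""Seeded synthetic bundles: corpus, lexicon, gold list, chemical–gene table.

A bundle plants ``n_planted`` "microbial" concepts whose per-document
occurrence probability inside the classified subset (``p_signal``) exceeds
the background probability (``p_background``), so the whole pipeline —
classification, extraction, ranking, evaluation, gene scoring — can be
exercised and its statistical behaviour measured without any external data.

Classified documents carry both classification keywords in the title;
background documents carry none, so keyword classification recovers the
classified subset exactly. Mentions are rendered from randomly chosen
synonyms and separated by filler words, so the truth manifest's per-concept
document frequencies are exactly reproducible by extraction.

Background occurrence rates for non-planted concepts are, by default,
heterogeneous (lognormal multipliers with mean 1 around ``p_background``),
giving the corpus the long tail of rare terms that real literature has; set
``background_dispersion = 0`` for homogeneous rates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .medline_io import Corpus, MedlineRecord, write_jsonl, write_medline_tagged
from .lexicon_ner import Lexicon, build_lexicon, write_lexicon_tsv

__all__ = [
    "SyntheticConfig",
    "ConceptTruth",
    "SyntheticBundle",
    "generate",
    "write_bundle",
    "read_manifest_tsv",
]

# Tokens that can never collide with classification keywords or each other.
_FILLERS = ("we", "measured", "and", "levels", "in", "the", "cohort", "samples")
_MULTIWORD_SUFFIXES = ("oxide", "sulfate", "ester", "amide", "salt")
_KEYWORD_PREFIXES = ("microb", "microfl", "metabol")
_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "ha", "ji", "ko", "lu", "ma",
    "ne", "pi", "qo", "ru", "sa", "te", "vu", "wa", "xe", "zo",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and probabilities of a synthetic bundle."""

    n_docs: int = 2000
    classified_fraction: float = 0.1
    n_concepts: int = 200
    n_planted: int = 20
    p_signal: float = 0.3
    p_background: float = 0.01
    synonyms_per_concept: int = 3
    multiword_fraction: float = 0.3
    background_dispersion: float = 2.0  # lognormal sigma; 0 = homogeneous
    n_genes: int = 50
    genes_per_chemical: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_background < self.p_signal <= 1:
            raise ValueError(
                "require 0 <= p_background < p_signal <= 1, got "
                f"p_background={self.p_background}, p_signal={self.p_signal}"
            )
        if not 0 < self.classified_fraction < 1:
            raise ValueError("classified_fraction must be in (0, 1)")
        if self.n_planted > self.n_concepts:
            raise ValueError("n_planted cannot exceed n_concepts")
        for name in (
            "n_docs", "n_concepts", "n_planted", "synonyms_per_concept",
            "n_genes", "genes_per_chemical",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.multiword_fraction <= 1:
            raise ValueError("multiword_fraction must be in [0, 1]")
        if self.background_dispersion < 0:
            raise ValueError("background_dispersion must be >= 0")


@dataclass(frozen=True)
class ConceptTruth:
    """Manifest row: what was planted and what occurrence counts it realized."""

    concept_id: str
    preferred_name: str
    planted: bool
    df: int
    dfc: int


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    corpus: Corpus
    classified_pmids: list[str]
    lexicon_entries: list[tuple[str, str, str]]
    gold_names: list[str]
    chem_gene_rows: list[tuple[str, str]]
    manifest: list[ConceptTruth]

    @property
    def lexicon(self) -> Lexicon:
        return build_lexicon(self.lexicon_entries)


def _pseudoword(rng: np.random.Generator, taken: set[str]) -> str:
    """A unique pronounceable token that cannot hit a classification keyword."""
    while True:
        n = int(rng.integers(3, 6))
        word = "".join(_SYLLABLES[i] for i in rng.integers(0, len(_SYLLABLES), n))
        if word in taken or word in _FILLERS or word in _MULTIWORD_SUFFIXES:
            continue
        if any(word.startswith(p) for p in _KEYWORD_PREFIXES):
            continue
        taken.add(word)
        return word


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a bundle; identical configs yield identical bundles."""
    rng = np.random.default_rng(config.seed)

    # --- vocabulary -------------------------------------------------------
    taken: set[str] = set()
    concept_ids = [f"M{i:04d}" for i in range(config.n_concepts)]
    preferred: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    lexicon_entries: list[tuple[str, str, str]] = []
    for cid in concept_ids:
        base = _pseudoword(rng, taken)
        multiword = rng.random() < config.multiword_fraction
        if multiword:
            suffix = _MULTIWORD_SUFFIXES[int(rng.integers(0, len(_MULTIWORD_SUFFIXES)))]
            name = f"{base} {suffix}"
            # base alone stays a synonym of the same concept, exercising
            # nested leftmost-longest resolution
            syns = [name, base]
        else:
            name = base
            syns = [name]
        while len(syns) < max(config.synonyms_per_concept, 1):
            syns.append(_pseudoword(rng, taken))
        preferred[cid] = name
        synonyms[cid] = syns
        lexicon_entries.extend((cid, name, syn) for syn in syns)

    planted_ids = concept_ids[: config.n_planted]
    planted_set = set(planted_ids)

    # --- occurrence rates -------------------------------------------------
    n_classified = max(1, round(config.n_docs * config.classified_fraction))
    classified_idx = np.sort(
        rng.choice(config.n_docs, size=n_classified, replace=False)
    )
    is_classified = np.zeros(config.n_docs, dtype=bool)
    is_classified[classified_idx] = True

    rates = np.empty((config.n_concepts, config.n_docs))
    for j, cid in enumerate(concept_ids):
        if cid in planted_set:
            rates[j, :] = config.p_background
            rates[j, is_classified] = config.p_signal
        elif config.background_dispersion > 0:
            sigma = config.background_dispersion
            w = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma)
            rates[j, :] = min(config.p_background * w, 1.0)
        else:
            rates[j, :] = config.p_background

    presence = rng.random((config.n_concepts, config.n_docs)) < rates

    # --- documents --------------------------------------------------------
    records: list[MedlineRecord] = []
    for d in range(config.n_docs):
        pmid = str(d + 1)
        if is_classified[d]:
            title = f"microbiota metabolism profiling of cohort {pmid}"
        else:
            title = f"clinical profiling of cohort {pmid}"
        mentions: list[str] = []
        for j in np.flatnonzero(presence[:, d]):
            syns = synonyms[concept_ids[j]]
            mentions.append(syns[int(rng.integers(0, len(syns)))])
        if mentions:
            abstract = "we measured " + " and ".join(mentions) + " in the cohort samples"
        else:
            abstract = "no analytes were measured in the cohort samples"
        records.append(
            MedlineRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                mesh_headings=["humans"],
            )
        )
    corpus = Corpus(records=records, source_label=f"synthetic(seed={config.seed})")
    classified_pmids = [str(int(i) + 1) for i in classified_idx]

    # --- manifest, gold, genes -------------------------------------------
    manifest = [
        ConceptTruth(
            concept_id=cid,
            preferred_name=preferred[cid],
            planted=cid in planted_set,
            df=int(presence[j, :].sum()),
            dfc=int(presence[j, is_classified].sum()),
        )
        for j, cid in enumerate(concept_ids)
    ]
    gold_names = [preferred[cid] for cid in planted_ids]

    gene_pool = [f"G{i:03d}" for i in range(config.n_genes)]
    chem_gene_rows: list[tuple[str, str]] = []
    if config.n_genes and config.genes_per_chemical:
        k = min(config.genes_per_chemical, config.n_genes)
        for cid in planted_ids:
            # use a synonym (not always the preferred name) as the table's
            # chemical key, exercising synonym-based mapping
            syns = synonyms[cid]
            chemical = syns[int(rng.integers(0, len(syns)))]
            genes = rng.choice(config.n_genes, size=k, replace=False)
            chem_gene_rows.extend((chemical, gene_pool[g]) for g in sorted(genes))

    return SyntheticBundle(
        config=config,
        corpus=corpus,
        classified_pmids=classified_pmids,
        lexicon_entries=lexicon_entries,
        gold_names=gold_names,
        chem_gene_rows=chem_gene_rows,
        manifest=manifest,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle to ``out_dir``; returns the emitted file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out_dir / "corpus.jsonl",
        "corpus_medline": out_dir / "corpus.medline",
        "lexicon": out_dir / "lexicon.tsv",
        "gold": out_dir / "gold.txt",
        "chem_gene": out_dir / "chem_gene.tsv",
        "manifest": out_dir / "truth_manifest.tsv",
    }
    write_jsonl(bundle.corpus, paths["corpus"])
    write_medline_tagged(bundle.corpus, paths["corpus_medline"])
    write_lexicon_tsv(bundle.lexicon_entries, paths["lexicon"])
    paths["gold"].write_text(
        "# planted concepts (preferred names)\n"
        + "".join(f"{name}\n" for name in bundle.gold_names),
        encoding="utf-8",
    )
    with paths["chem_gene"].open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["chemical", "gene"])
        writer.writerows(bundle.chem_gene_rows)
    with paths["manifest"].open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["concept_id", "preferred_name", "planted", "df", "dfc"])
        for row in bundle.manifest:
            writer.writerow(
                [row.concept_id, row.preferred_name, int(row.planted), row.df, row.dfc]
            )
    return paths


def read_manifest_tsv(path: str | Path) -> list[ConceptTruth]:
    path = Path(path)
    rows: list[ConceptTruth] = []
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            rows.append(
                ConceptTruth(
                    concept_id=row["concept_id"],
                    preferred_name=row["preferred_name"],
                    planted=bool(int(row["planted"])),
                    df=int(row["df"]),
                    dfc=int(row["dfc"]),
                )
            )
    return rows
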