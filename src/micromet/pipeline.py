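"""End-to-end orchestration: classify → extract → rank → evaluate → genes.

A single config drives the whole run. Outputs are written per stage and a
machine-readable ``run_report.json`` collects every count and setting, so
each reported number can be recomputed from the emitted intermediate files.
Any stage failure aborts the run with the stage name; the report written on
failure is labeled partial.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import classify as _classify
from .evaluate import (
    DEFAULT_RECALL_CUTOFFS,
    GoldStandard,
    load_gold,
    pr_curve,
    precision_at_k,
    prf,
)
from .gene_interactions import load_aliases, load_chem_gene, map_metabolites, score_genes, write_gene_scores
from .lexicon_ner import Lexicon, compute_df, extract_concepts, read_lexicon_tsv, write_df_tsv
from .medline_io import FIELDS, Corpus, read_jsonl, read_medline_tagged, write_jsonl
from .prioritize import RankedList, score_table, write_ranked_tsv

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run",
    "export_curation_sheet",
    "merge_curation_labels",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    corpus: str
    lexicon: str
    gold: str
    out_dir: str
    chem_gene: str | None = None
    aliases: str | None = None
    curated_gold: str | None = None  # optional second gold list, unioned for gene scoring
    fields: tuple[str, ...] = FIELDS
    match_mode: str = "token-prefix"
    rank_method: str = "rank4"
    top_k: tuple[int, ...] = (20, 50, 70, 100)
    recall_cutoffs: tuple[float, ...] = DEFAULT_RECALL_CUTOFFS
    min_chem_score: float | None = None
    curation_top_k: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        for key in ("fields", "top_k", "recall_cutoffs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_corpus(path: str | Path) -> Corpus:
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        return read_jsonl(path)
    return read_medline_tagged(path)


def run(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"settings": _settings_dict(config), "status": "partial"}
    stage = "init"
    try:
        stage = "load"
        corpus = _load_corpus(config.corpus)
        report["counts"] = {"corpus": len(corpus)}

        stage = "classify"
        microbial_ks = _classify.preset_keywords("microbial", config.match_mode)
        metabolism_ks = _classify.preset_keywords("metabolism", config.match_mode)
        microbial = _classify.classify_corpus(corpus, microbial_ks, config.fields)
        metabolism = _classify.classify_corpus(microbial, metabolism_ks, config.fields)
        write_jsonl(microbial, out_dir / "classified_microbial.jsonl")
        write_jsonl(metabolism, out_dir / "classified_metabolism.jsonl")
        report["counts"]["classified_microbial"] = len(microbial)
        report["counts"]["classified_metabolism"] = len(metabolism)

        stage = "extract"
        lexicon = read_lexicon_tsv(config.lexicon)
        df_table = compute_df(corpus, metabolism, lexicon, config.fields)
        write_df_tsv(df_table, out_dir / "df.tsv")
        report["counts"]["extracted_concepts"] = len(df_table)

        stage = "rank"
        ranked = score_table(df_table, config.rank_method)
        write_ranked_tsv(ranked, out_dir / f"ranked_{config.rank_method}.tsv")

        stage = "evaluate"
        gold = load_gold(config.gold)
        rows = []
        for label, subset in (
            ("unclassified", corpus),
            ("classified_microbial", microbial),
            ("classified_metabolism", metabolism),
        ):
            names = _extracted_names(subset, lexicon, config.fields)
            metrics = prf(names, gold)
            rows.append(
                {
                    "subset": label,
                    "articles": len(subset),
                    "extracted_metabolites": len(names),
                    "precision": metrics.precision,
                    "recall": metrics.recall,
                    "f1": metrics.f1,
                }
            )
        _write_eval_rows(rows, out_dir / "evaluation.tsv")
        report["evaluation"] = rows

        curve = pr_curve(ranked, gold, config.recall_cutoffs)
        _write_pr_points(curve, out_dir / "pr_points.tsv")
        report["pr_curve"] = [
            {"recall_cutoff": p.recall_cutoff, "precision": p.precision, "reached": p.reached}
            for p in curve
        ]
        at_k = {
            k: precision_at_k(ranked, gold, k) for k in config.top_k if k <= len(ranked)
        }
        _write_at_k(at_k, out_dir / "precision_at_k.tsv")
        report["precision_at_k"] = {str(k): v for k, v in at_k.items()}

        if config.curation_top_k:
            stage = "curation_sheet"
            export_curation_sheet(
                ranked, metabolism, lexicon, config.curation_top_k,
                out_dir / "curation_sheet.tsv", config.fields,
            )

        if config.chem_gene:
            stage = "genes"
            table = load_chem_gene(config.chem_gene, min_score=config.min_chem_score)
            aliases = load_aliases(config.aliases) if config.aliases else None
            gene_gold = gold
            if config.curated_gold:
                gene_gold = gold.union(load_gold(config.curated_gold))
            mapping = map_metabolites(sorted(gene_gold.members), table, lexicon, aliases)
            scores = score_genes(mapping, table)
            write_gene_scores(scores, out_dir / "gene_scores.tsv")
            report["counts"]["mapped_metabolites"] = len(mapping.mapped)
            report["counts"]["unmapped_metabolites"] = len(mapping.unmapped)
            report["counts"]["scored_genes"] = len(scores)
            report["top_genes"] = [
                {"gene": gs.gene, "score": gs.score} for gs in scores[:20]
            ]

        report["status"] = "complete"
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        report["failed_stage"] = stage
        (out_dir / "run_report.json").write_text(
            json.dumps(report, indent=2), encoding="utf-8"
        )
        raise PipelineError(stage, exc) from exc

    (out_dir / "run_report.json").write_text(
        json.dumps(report, indent=2), encoding="utf-8"
    )
    return report


def _settings_dict(config: PipelineConfig) -> dict:
    settings = asdict(config)
    for key in ("fields", "top_k", "recall_cutoffs"):
        settings[key] = list(settings[key])
    return settings


def _extracted_names(
    corpus: Corpus, lexicon: Lexicon, fields: Sequence[str]
) -> set[str]:
    names: set[str] = set()
    for rec in corpus:
        for cid in extract_concepts(rec, lexicon, fields):
            names.add(lexicon.preferred_name(cid))
    return names


def _write_eval_rows(rows: list[dict], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.DictWriter(
            handle,
            fieldnames=[
                "subset", "articles", "extracted_metabolites",
                "precision", "recall", "f1",
            ],
            delimiter="\t",
            lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(rows)


def _write_pr_points(points, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["recall_cutoff", "precision", "reached"])
        for p in points:
            writer.writerow([p.recall_cutoff, repr(p.precision), int(p.reached)])


def _write_at_k(at_k: dict[int, float], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["k", "precision"])
        for k, v in sorted(at_k.items()):
            writer.writerow([k, repr(v)])


def export_curation_sheet(
    ranked: RankedList,
    corpus: Corpus,
    lexicon: Lexicon,
    top_k: int,
    path: str | Path,
    fields: Iterable[str] = FIELDS,
) -> None:
    """Write the manual-review sheet for the top ``top_k`` ranked concepts.

    One row per concept with its counts, score, the PMIDs of the (classified)
    documents containing it, and an empty label column per curator.
    """
    if top_k > len(ranked):
        raise ValueError(f"top_k={top_k} exceeds ranked list length {len(ranked)}")
    fields = tuple(fields)
    wanted = {item.concept_id for item in ranked[:top_k]}
    pmids_by_concept: dict[str, list[str]] = {cid: [] for cid in wanted}
    for rec in corpus:
        for cid in extract_concepts(rec, lexicon, fields):
            if cid in wanted:
                pmids_by_concept[cid].append(rec.pmid)
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["rank", "preferred_name", "dfc", "df", "score", "pmids",
             "curated_label_1", "curated_label_2"]
        )
        for item in ranked[:top_k]:
            writer.writerow(
                [item.rank, item.preferred_name, item.dfc, item.df,
                 repr(item.score), ";".join(pmids_by_concept[item.concept_id]),
                 "", ""]
            )


def merge_curation_labels(labels_1: Sequence[str], labels_2: Sequence[str]) -> list[bool]:
    """Consensus rule for two curators: accepted only if both say "yes"."""
    if len(labels_1) != len(labels_2):
        raise ValueError("curator label columns differ in length")
    return [
        a.strip().lower() == "yes" and b.strip().lower() == "yes"
        for a, b in zip(labels_1, labels_2)
    ]
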