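"""Document-frequency ranking of extracted concepts.

Four scores, all computed from a concept's document frequency in the
classified subset (dfc) and in the full corpus (df):

* rank1 = dfc
* rank2 = dfc / (df - dfc)
* rank3 = dfc / ln(df - dfc)
* rank4 = dfc^2 / (df - dfc)

rank2/rank4 are undefined when df == dfc and rank3 when df - dfc <= 1; the
denominators are floored at 1 in those cases, which keeps every score finite
and monotone. Floored concepts are counted and logged by score_table.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Callable, NamedTuple

from .lexicon_ner import DocumentFrequencyTable

__all__ = [
    "rank1",
    "rank2",
    "rank3",
    "rank4",
    "RANK_METHODS",
    "RankedItem",
    "RankedList",
    "score_table",
    "read_ranked_tsv",
    "write_ranked_tsv",
]

logger = logging.getLogger(__name__)


def _check(dfc: float, df: float) -> None:
    if not 0 <= dfc <= df:
        raise ValueError(f"require 0 <= dfc <= df, got dfc={dfc}, df={df}")


def rank1(dfc: float, df: float) -> float:
    """Frequency in classified documents."""
    _check(dfc, df)
    return float(dfc)


def rank2(dfc: float, df: float) -> float:
    """Classified frequency offset by background frequency."""
    _check(dfc, df)
    return dfc / max(df - dfc, 1)


def rank3(dfc: float, df: float) -> float:
    """Like rank2 but the background offset is logarithmic (natural log)."""
    _check(dfc, df)
    rest = df - dfc
    denom = math.log(rest) if rest > 1 else 1.0
    return dfc / max(denom, 1.0)


def rank4(dfc: float, df: float) -> float:
    """Like rank2 with the classified signal boosted quadratically."""
    _check(dfc, df)
    return dfc * dfc / max(df - dfc, 1)


RANK_METHODS: dict[str, Callable[[float, float], float]] = {
    "rank1": rank1,
    "rank2": rank2,
    "rank3": rank3,
    "rank4": rank4,
}


class RankedItem(NamedTuple):
    rank: int  # 1-based position
    concept_id: str
    preferred_name: str
    score: float
    dfc: int
    df: int


class RankedList:
    """Concepts in non-increasing score order with consecutive positions."""

    def __init__(self, items: list[RankedItem], method: str = "") -> None:
        for pos, item in enumerate(items, start=1):
            if item.rank != pos:
                raise ValueError(f"rank positions must be consecutive from 1, got {item.rank} at {pos}")
            if pos > 1 and item.score > items[pos - 2].score:
                raise ValueError("scores must be non-increasing with rank position")
        self.items = items
        self.method = method

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, idx):
        return self.items[idx]

    def concept_ids(self) -> list[str]:
        return [item.concept_id for item in self.items]

    def preferred_names(self) -> list[str]:
        return [item.preferred_name for item in self.items]


def score_table(table: DocumentFrequencyTable, method: str) -> RankedList:
    """Score every concept in ``table`` and sort deterministically.

    Order: score descending, ties by dfc descending, then preferred name
    ascending — a reproducible total order.
    """
    if method not in RANK_METHODS:
        raise ValueError(f"unknown ranking method {method!r}; choose from {sorted(RANK_METHODS)}")
    fn = RANK_METHODS[method]
    scored = [
        (fn(rec.dfc, rec.df), rec) for rec in table.records.values()
    ]
    if method in ("rank2", "rank3", "rank4"):
        floored = sum(1 for _, rec in scored if rec.df - rec.dfc <= (1 if method == "rank3" else 0))
        if floored:
            logger.warning(
                "%s: denominator floor applied to %d concept(s)", method, floored
            )
    scored.sort(key=lambda pair: (-pair[0], -pair[1].dfc, pair[1].preferred_name))
    items = [
        RankedItem(
            rank=pos,
            concept_id=rec.concept_id,
            preferred_name=rec.preferred_name,
            score=score,
            dfc=rec.dfc,
            df=rec.df,
        )
        for pos, (score, rec) in enumerate(scored, start=1)
    ]
    return RankedList(items, method=method)


def write_ranked_tsv(ranked: RankedList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "concept_id", "preferred_name", "score", "dfc", "df"])
        for item in ranked:
            writer.writerow(
                [item.rank, item.concept_id, item.preferred_name,
                 repr(item.score), item.dfc, item.df]
            )


def read_ranked_tsv(path: str | Path) -> RankedList:
    path = Path(path)
    items: list[RankedItem] = []
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            items.append(
                RankedItem(
                    rank=int(row["rank"]),
                    concept_id=row["concept_id"],
                    preferred_name=row["preferred_name"],
                    score=float(row["score"]),
                    dfc=int(row["dfc"]),
                    df=int(row["df"]),
                )
            )
    return RankedList(items)
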