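"""Evaluation against a gold-standard metabolite list.

Gold members and candidate names are joined by the shared normalization, so
"Butyric Acid" in a gold file matches the lexicon concept "butyric acid".
Provides set-level precision/recall/F1, ranked precision@k, precision at
fixed recall cutoffs (step interpolation: precision at the minimal depth
achieving the cutoff), and the simple comparison statistics (percent change,
fold enrichment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .normalize import normalize_text
from .prioritize import RankedList

__all__ = [
    "DEFAULT_RECALL_CUTOFFS",
    "GoldStandard",
    "EvaluationMetrics",
    "PRPoint",
    "load_gold",
    "prf",
    "f1_of",
    "precision_at_k",
    "pr_curve",
    "percent_change",
    "fold_enrichment",
    "plot_pr_curves",
]

logger = logging.getLogger(__name__)

#: The 11 recall cutoffs used for PR curves.
DEFAULT_RECALL_CUTOFFS: tuple[float, ...] = (
    0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)


@dataclass(frozen=True)
class GoldStandard:
    """A named set of gold metabolite names, stored in normalized form."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_names(cls, name: str, names: Iterable[str]) -> "GoldStandard":
        members = frozenset(
            norm for norm in (normalize_text(n) for n in names) if norm
        )
        return cls(name=name, members=members)

    def union(self, other: "GoldStandard", name: str | None = None) -> "GoldStandard":
        """Merge two gold standards; overlapping members collapse."""
        overlap = self.members & other.members
        if overlap:
            logger.info(
                "gold union %s+%s: %d overlapping member(s)",
                self.name, other.name, len(overlap),
            )
        return GoldStandard(
            name=name or f"{self.name}+{other.name}",
            members=self.members | other.members,
        )

    def __contains__(self, name: str) -> bool:
        return normalize_text(name) in self.members

    def __len__(self) -> int:
        return len(self.members)


def load_gold(path: str | Path, name: str | None = None) -> GoldStandard:
    """Read a gold list: one metabolite name per line, '#' comments allowed."""
    path = Path(path)
    names: list[str] = []
    with path.open(encoding="utf-8") as handle:
        for line in handle:
            line = line.split("#", 1)[0].strip()
            if line:
                names.append(line)
    return GoldStandard.from_names(name or path.stem, names)


@dataclass(frozen=True)
class EvaluationMetrics:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


def prf(extracted: Iterable[str], gold: GoldStandard) -> EvaluationMetrics:
    """Precision/recall/F1 of an extracted name set against ``gold``.

    Names are normalized before comparison; empty extraction gives
    precision 0 by convention.
    """
    if not gold.members:
        raise ValueError("gold standard must be non-empty")
    extracted_norm = {
        norm for norm in (normalize_text(n) for n in extracted) if norm
    }
    tp = len(extracted_norm & gold.members)
    fp = len(extracted_norm - gold.members)
    fn = len(gold.members - extracted_norm)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    return EvaluationMetrics(
        precision=precision,
        recall=recall,
        f1=f1_of(precision, recall),
        tp=tp,
        fp=fp,
        fn=fn,
    )


def f1_of(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError(
            f"precision and recall must be in [0, 1], got {precision}, {recall}"
        )
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _gold_flags(ranked: RankedList, gold: GoldStandard) -> list[bool]:
    return [normalize_text(item.preferred_name) in gold.members for item in ranked]


def precision_at_k(ranked: RankedList, gold: GoldStandard, k: int) -> float:
    """Fraction of the first ``k`` ranked concepts that are gold members."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k must be in [1, {len(ranked)}], got {k}")
    flags = _gold_flags(ranked, gold)[:k]
    return sum(flags) / k


class PRPoint(NamedTuple):
    recall_cutoff: float
    precision: float
    reached: bool  # False when ranked list never attains the cutoff


def pr_curve(
    ranked: RankedList,
    gold: GoldStandard,
    cutoffs: Sequence[float] = DEFAULT_RECALL_CUTOFFS,
) -> list[PRPoint]:
    """Precision at each recall cutoff over a ranked list.

    For each cutoff the precision is taken at the smallest depth whose recall
    meets it. Cutoffs the list never reaches (gold members absent from the
    ranking) are emitted with full-depth precision and ``reached=False``.
    """
    if not gold.members:
        raise ValueError("gold standard must be non-empty")
    cutoffs = tuple(cutoffs)
    if any(not 0 < c <= 1 for c in cutoffs):
        raise ValueError("recall cutoffs must lie in (0, 1]")
    if list(cutoffs) != sorted(cutoffs) or len(set(cutoffs)) != len(cutoffs):
        raise ValueError("recall cutoffs must be strictly increasing")

    flags = _gold_flags(ranked, gold)
    n_gold = len(gold.members)
    points: list[PRPoint] = []
    tp = 0
    depth = 0
    it = iter(enumerate(flags, start=1))
    full_precision = sum(flags) / len(flags) if flags else 0.0
    for cutoff in cutoffs:
        reached = False
        while tp / n_gold < cutoff:
            nxt = next(it, None)
            if nxt is None:
                break
            depth, flag = nxt
            tp += flag
        if tp / n_gold >= cutoff and depth > 0:
            reached = True
            points.append(PRPoint(cutoff, tp / depth, True))
        else:
            points.append(PRPoint(cutoff, full_precision, False))
            logger.warning(
                "pr_curve: recall cutoff %.2f not attainable (max recall %.3f)",
                cutoff, sum(flags) / n_gold,
            )
    return points


def percent_change(old_value: float, new_value: float) -> float:
    """Signed percent change from ``old_value`` to ``new_value``."""
    if old_value <= 0:
        raise ValueError(f"old_value must be positive, got {old_value}")
    return 100.0 * (new_value - old_value) / old_value


def fold_enrichment(baseline: float, improved: float) -> float:
    """Ratio of an improved value to its baseline."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return improved / baseline


def plot_pr_curves(curves: dict[str, list[PRPoint]], path: str | Path) -> None:
    """Plot one PR curve per ranking method to ``path`` (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, points in curves.items():
        ax.plot(
            [p.recall_cutoff for p in points],
            [p.precision for p in points],
            marker="o",
            label=label,
        )
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
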