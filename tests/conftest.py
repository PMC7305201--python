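from __future__ import annotations

import pytest

from micromet.lexicon_ner import build_lexicon
from micromet.medline_io import Corpus, MedlineRecord


@pytest.fixture
def butyrate_lexicon():
    """Concept C1 (butyric acid) plus a nested multi-word pair for C2/C3."""
    return build_lexicon(
        [
            ("C1", "butyric acid", "butyrate"),
            ("C1", "butyric acid", "propylformate"),
            ("C2", "trimethylamine", "trimethylamine"),
            ("C3", "trimethylamine n-oxide", "tmao"),
        ]
    )


@pytest.fixture
def small_corpus():
    return Corpus(
        records=[
            MedlineRecord(
                pmid="1",
                title="Gut microbiota and health",
                abstract="propylformate was elevated in metabolite profiles",
            ),
            MedlineRecord(
                pmid="2",
                title="Antimicrobial resistance genes",
                abstract="trimethylamine n-oxide levels were measured",
            ),
            MedlineRecord(
                pmid="3",
                title="Cohort survey",
                abstract="butyrate and trimethylamine were detected",
                chemicals=["butyric acid"],
            ),
            MedlineRecord(pmid="4", title="Empty content record"),
        ],
        source_label="fixture",
    )
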