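# micromet

Mining microbial-metabolite signal from bibliographic corpora: keyword
classification of records, dictionary-based named-entity recognition against
a metabolite synonym lexicon, document-frequency signal prioritization,
ranked evaluation against a gold-standard list, and scoring of human genes
by the number of associated metabolites. A seeded synthetic-bundle generator
makes every stage testable end-to-end without any external downloads.

## Workflow

```
corpus ──classify──▶ microbial subset ──classify──▶ metabolism subset
   │                                                     │
   └───────────────extract (lexicon NER)─────────────────┘
                           │
                     df / dfc table ──rank (rank1..rank4)──▶ ranked list
                           │                                    │
                        evaluate (PRF, PR curve, precision@k) ◀─┘
                           │
                        genes (chemical–gene table → gene scores)
```

The four ranking scores are computed from each concept's document frequency
in the classified subset (`dfc`) and in the full corpus (`df`):
`rank1 = dfc`, `rank2 = dfc/(df−dfc)`, `rank3 = dfc/ln(df−dfc)`,
`rank4 = dfc²/(df−dfc)` (denominators floored at 1 where undefined).

## CLI

Each stage is a subcommand of `micromet` (see `micromet --help`):

```sh
micromet simulate --seed 1 --out bundle/          # synthetic corpus + lexicon + gold + genes
micromet classify --stage microbial  --in bundle/corpus.jsonl --out microbial.jsonl
micromet classify --stage metabolism --in microbial.jsonl     --out metabolism.jsonl
micromet extract  --lexicon bundle/lexicon.tsv --all bundle/corpus.jsonl \
                  --classified metabolism.jsonl --out df.tsv
micromet rank     --df df.tsv --method rank4 --out ranked.tsv
micromet eval     --ranked ranked.tsv --gold bundle/gold.txt --at-k 20,50,70,100
micromet genes    --metabolites bundle/gold.txt --chem-gene bundle/chem_gene.tsv \
                  --lexicon bundle/lexicon.tsv --out gene_scores.tsv
```

or run everything from one YAML config:

```sh
micromet run-all --config pipeline.yaml      # writes run_report.json + per-stage files
```

Config keys mirror `micromet.pipeline.PipelineConfig` (corpus, lexicon,
gold, chem_gene, out_dir, rank_method, top_k, recall_cutoffs, ...).

## File formats

All formats are plain text: MEDLINE tagged exports or JSON-lines corpora;
TSV for the lexicon (`concept_id  preferred_name  synonym`), document
frequencies (`concept_id  preferred_name  df  dfc`), ranked lists, chemical–
gene pairs (`chemical  gene[  score]`) and gene scores; gold standards are
one name per line with `#` comments.

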