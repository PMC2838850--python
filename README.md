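# cgckit

Keyword-weighted candidate gene analysis for quantitative trait locus (QTL)
studies. The package scores genes for disease relevance by weighted keyword
matching over per-gene descriptive records ("CGC scores"), tests whether
high-scoring genes concentrate inside QTL regions, and detects QTL pairs from
two crosses that share an unexpectedly high number of cross-referenced gene
pairs. A seeded synthetic-data generator produces every input format with
controllable enrichment effects, so the whole pipeline runs and is testable
offline.

## Modules

| module | role |
| --- | --- |
| `cgckit.keyword_model` | keyword weights (relevance indices) from literature co-occurrence counts |
| `cgckit.cgc_scoring` | per-gene CGC scores, ranking, minimum-score filtering |
| `cgckit.genome_partition` | inside/outside-QTL classification, score strata, 1-df goodness-of-fit tests |
| `cgckit.qtl_connectivity` | cross-cross gene-pair counting, expected counts, Yates chi-square flags |
| `cgckit.synthetic_data` | seeded generators for catalogs, QTLs, corpora and link tables |
| `cgckit.cli` | the `cgckit` command |

## CLI

```sh
# generate a synthetic universe (all file formats the pipeline consumes)
cgckit simulate --seed 7 --out-dir sim/

# score the corpus against the keyword file
cgckit score --keywords sim/keywords.tsv --corpus sim/corpus.jsonl --out scored.tsv

# stratified inside/outside-QTL report (TSV, text and JSON summary)
cgckit partition --catalog sim/catalog.tsv --qtls sim/qtls.tsv \
    --scored scored.tsv --out-prefix out/partition

# QTL-pair connectivity tests plus the high-score gene-pair table
cgckit connect --catalog sim/catalog.tsv --qtls sim/qtls.tsv \
    --corpus sim/corpus.jsonl --scored scored.tsv --out-prefix out/connect

# or everything from one YAML config
cgckit report --config run.yaml --out-dir out/
```

Every subcommand accepts `--config` (YAML with the same keys as the flags)
and `--version`; exit codes are 0 on success, 1 for usage/validation errors,
2 for data errors.

Input formats: keyword TSV (`term<TAB>weight`), co-occurrence TSV
(`term<TAB>n_keyword<TAB>n_joint`), gene catalog TSV
(`symbol<TAB>chrom<TAB>start<TAB>stop`, 1-based inclusive; `.bed` accepted and
converted), QTL TSV (`symbol<TAB>cross<TAB>chrom<TAB>start<TAB>stop[<TAB>lod<TAB>p]`),
and a JSON-lines record corpus (`{"symbol", "text", "links"}`; a directory of
per-gene `.txt` files plus a links TSV also works).

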