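# dilitext

Controlled-vocabulary text mining and gradient-boosted classification of
adverse-event (DILI) risk from free-text documents.

Instead of generic stop-word removal, the pipeline keeps **only** tokens and
phrases found in a user-supplied preferred-term dictionary (e.g., a MedDRA
PT or FMQ export — licensed vocabularies are never shipped), canonicalizes
them through an explicit recoding table, builds a sparse TF-IDF
document-term matrix, and classifies documents with a gradient-boosted tree
ensemble evaluated by repeated stratified cross-validation.

## Components

| module | role |
| --- | --- |
| `dilitext.vocab` | dictionary/recoding loading, tokenization, longest-match whitelist term extraction |
| `dilitext.dtm` | sparse count matrix, minimum-frequency filter, TF-IDF (`tf × log10(N/df)`), vocabulary alignment, MatrixMarket I/O |
| `dilitext.modeling` | booster configuration (defaults `max_depth=3, subsample=1, colsample=1, min_child_weight=1, alpha=0, lambda=1, learning_rate=0.1, iterations=30`), iteration-history selection, Latin-hypercube autotune, splits/gain/cover importance |
| `dilitext.evaluation` | repeated stratified fold plans (k=5, R=10), ACC/AUC/MCC/RMSE/sensitivity/specificity/precision, profit-matrix thresholds, probability-decile consistency, multi-learner screening |
| `dilitext.prediction` | scoring new documents with frozen training IDF; cross-corpus transfer on a shared vocabulary |
| `dilitext.synthetic` | toy dictionaries and corpora with planted label-associated signal terms |
| `dilitext.cli` | `dilitext` command-line interface |

## CLI

```sh
# generate a synthetic corpus + dictionary + recoding map
dilitext simulate --n-docs 600 --vocabulary-size 500 --seed 1 --out run/sim

# full pipeline: extract -> TF-IDF -> 10x5-fold CV -> reports
dilitext evaluate --corpus run/sim/corpus.csv \
    --dictionary run/sim/dictionary.txt --recoding run/sim/recoding.tsv \
    --folds 5 --repeats 10 --seed 1 --out run/eval

# train and save a model, then score another corpus with frozen IDF
dilitext train   --corpus run/sim/corpus.csv --dictionary run/sim/dictionary.txt \
    --recoding run/sim/recoding.tsv --seed 1 --out run/model
dilitext predict --model run/model/model --corpus run/sim/corpus.csv \
    --dictionary run/sim/dictionary.txt --recoding run/sim/recoding.tsv \
    --out run/pred

# nested-CV screening of learner families
dilitext screen --corpus run/sim/corpus.csv --dictionary run/sim/dictionary.txt \
    --recoding run/sim/recoding.tsv --out run/screen
```

Every output directory contains a `manifest.json` (input checksums, config,
seed, version) sufficient to re-run the command reproducibly.

Corpus format: CSV/TSV with columns `doc_id`, `text`, optional `label`
(0/1) and `source`. Dictionary: one term per line (or TSV with a named
column). Recoding: two-column TSV `source<TAB>canonical`; chains are
resolved, cycles rejected.

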