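# enaudit

Auditing and scoring toolkit for **entity normalization** (EN) — the task
of linking text mentions to concepts of a reference ontology.

What it provides:

* **Metrics** (`enaudit.scoring`) — classic accuracy, top-k accuracy, an
  accuracy generalized to multi-normalization (a mention annotated by
  several concepts), a variant that additionally penalizes
  over-prediction via a `max(n_i, p_i)` denominator, and the lenient
  "any correct concept earns the full point" variant used by some
  published evaluation scripts (composite mentions still require all
  concepts).
* **Dataset-bias indicators** (`enaudit.indicators`) — few-shot (FSL)
  statistics of mentions-per-concept, multi-normalization / NIL /
  ambiguity rates within a fold pool, and redundancy / zero-shot (ZSL)
  rates between training and test material, with every denominator
  reported.
* **A two-sieve baseline normalizer** (`enaudit.baseline`) — (1)
  lexicon of lowercased + Porter-stemmed ontology labels augmented with
  training surfaces (most-frequent-concept rule), exact match; (2) a
  ridge linear projection of mean-token word2vec mention embeddings onto
  label embeddings, cosine-nearest-label prediction over an optionally
  restricted concept subset.
* **Readers/writers** (`enaudit.io`) — BioNLP-ST standoff (.a1/.a2 +
  .txt), PubTator, OBO 1.2, CTD MEDIC TSV, word2vec text/binary
  embeddings, prediction TSV / .a2.
* **Ablation harness** (`enaudit.experiments`) — ontology subsetting to
  used concepts (broken hierarchy left as is), generic preprocessing
  toggles (lowercase, punctuation, stopwords, stem/lemma, pluggable
  hooks), and a combined JSON/Markdown bias-audit report.
* **Synthetic data** (`enaudit.synthetic`) — seeded generator of toy
  ontologies, corpora with exact requested redundancy/ZSL (and
  near-exact ambiguity/multi-norm/NIL) rates, and clustered toy
  embeddings, so everything above is testable offline.

## CLI

All verbs live under a single `enaudit` entry point:

```bash
# generate an offline synthetic dataset (standoff + OBO + word2vec text)
enaudit simulate --seed 17 --out sim/

# bias audit: indicators + baseline accuracy under ontology subsets
enaudit audit --train sim/train --dev sim/dev --test sim/test \
    --ontology sim/ontology.obo --embeddings sim/embeddings.vec \
    --policy exact --out report.json --markdown report.md

# run the two-sieve baseline
enaudit predict --train sim/train --test sim/test \
    --ontology sim/ontology.obo --embeddings sim/embeddings.vec \
    --subset full --weak-supervision off --out pred.tsv

# score a prediction file (eq1 | eq3 | eq4 | topk:k | lenient)
enaudit score --gold sim/test --pred pred.tsv --ontology sim/ontology.obo \
    --metric eq4 --train sim/train --breakdown zsl,redundant,ambiguous,multinorm

# restrict an ontology to the concepts used by given splits
enaudit subset --splits sim/train,sim/dev --ontology sim/ontology.obo --out sub.obo
```

Corpus arguments are directories (standoff) or files (PubTator);
ontologies are `.obo` or MEDIC `.tsv`.  Standoff corpora are filtered to
`Habitat` entities by default (`--types all` keeps everything).
`predict` writes a `<out>.meta.json` recording stemmer, tokenizer, ridge
strength and sieve statistics.

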