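# chemstitch

Chemical named-entity recognition with no hand-crafted rules.

Chemical mentions — systematic names like
`2-amino-1-methyl-6-phenylimidazo[4,5-b]pyridine`, formulae, abbreviations,
identifiers, trivial names — defeat conventional tokenisers and
dictionary/regex NER systems because their morphology differs radically
from ordinary prose.  `chemstitch` replaces every hand-written rule with a
trained component:

* a **break-and-stitch tokeniser**: deliberate over-segmentation with
  `\w+|[^\s\w]`, followed by a character-level CNN-GRU model that marks
  *stitch points* — fragments to merge back into entity-sized tokens;
* **bin-packing stateful batching**: full-length texts (no sentence
  splitting) are packed into equal-load bins, concatenated into
  super-sequences and cut into fixed windows, so a *half-stateful*
  bidirectional RNN — forward state carried across windows, backward state
  reset — reads each text as one long sequence; the construction is exactly
  invertible;
* a **dual-embedding NER network**: per-token character-level embeddings
  (linear char embedding + biGRU) and word embeddings feed parallel CNN
  stacks, a half-stateful biGRU trunk, and two coupled sigmoid heads
  predicting per token *s* = "begins an entity" and *e* = "part of an
  entity", with the start head's features scaled step-wise by the part
  head's probability;
* **ensemble averaging** of independently trained networks, threshold
  decoding of (s, e) runs into character-offset spans, and **exact-match
  CEM scoring** (a prediction counts only if both offsets match a gold
  span) with per-class recalls.

Everything runs on a compact numpy automatic-differentiation backend shipped
with the package (`chemstitch.nn`) — no deep-learning framework required —
and a synthetic corpus generator emulates the tab-separated corpus dialect
(abstracts: `id<TAB>title<TAB>abstract`; annotations:
`id<TAB>T|A<TAB>start<TAB>end<TAB>text<TAB>class`) so the whole pipeline is
testable at desk scale.  See `docs/methods.md` for the models and
conventions in detail.

## Worked example

Generate a corpus, train a small one-member pipeline, annotate and score:

```bash
chemstitch synth --out corpus --seed 1 --n-documents 50
cat > small.yaml <<'YAML'
tokenizer:
  char_embedding_dim: 16
  conv_filters: 16
  rnn_cells: 8
  batch_size: 16
  window_length: 96
  epochs: 20
ner:
  word_embedding_dim: 16
  char_embedding_dim: 16
  char_rnn_cells: 8
  conv_filters: 16
  trunk_rnn_cells: 8
  head_rnn_cells: 8
  min_frequency: 2
  epochs: 40
  ensemble_size: 1
  batch_size: 16
  window_length: 32
  learning_rate: 0.003
YAML
chemstitch train-ner --config small.yaml --abstracts corpus/abstracts.tsv \
    --annotations corpus/annotations.tsv --out model --seed 1
chemstitch annotate --model model --abstracts corpus/abstracts.tsv --out pred.tsv
chemstitch evaluate --abstracts corpus/abstracts.tsv \
    --gold corpus/annotations.tsv --predicted pred.tsv
```

The evaluation prints a report of the form

```
CEM exact-match scores
  precision   84.92%
  recall      92.64%
  F1          88.61%
  TP 214  FP 38  FN 17

  class            recall  entities
  MULTIPLE          0.00%         1
  IDENTIFIER      100.00%         5
  FAMILY           84.38%        32
  FORMULA         100.00%        32
  ABBREVIATION    100.00%        34
  SYSTEMATIC       92.86%        56
  TRIVIAL          90.14%        71
```

(this scores the model on its own 50-document training corpus — small and
optimistic; the held-out numbers come from the reproduction script below).
Precision,
recall and F1 follow the exact-boundary rule; per-class rows give the recall
and the gold count for every class present.  The library API mirrors the
commands: `chemstitch.synthetic.generate_corpus`,
`chemstitch.pipeline.train_pipeline`, `NerPipeline.annotate`,
`chemstitch.evaluation.score_cem`.

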