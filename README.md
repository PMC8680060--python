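# clintagger

Clinical named-entity recognition and concept normalization for
Spanish-style clinical case text, built around three pieces:

1. **BMEWO-V tag codec** — converts BRAT standoff annotations (possibly
   *nested*: "calcio" inside "calcio iónico corregido") to one tag per
   token and back. Besides B/M/E/W/O, a **V** tag marks tokens covered by
   more than one mention, so a flat sequence model can learn one level of
   nesting. For `T` entity types the inventory has `5·T + 1` tags.
2. **Character + word + sense Bi-LSTM-CRF tagger** — a character-level
   Bi-LSTM feeds, together with word and sense (`token|POS`) embeddings,
   a sentence-level Bi-LSTM whose emissions enter a linear-chain CRF
   (forward-algorithm likelihood, Viterbi decoding, BMEWO-V transition
   constraints). Implemented in numpy with hand-derived, numerically
   verified backpropagation; training is per-sentence SGD and
   bit-reproducible for a fixed seed.
3. **Two-stage concept normalizer** — lowercase → abbreviation expansion →
   exact dictionary match → bounded Levenshtein search → thresholded fuzzy
   search (similarity `1 − d/max(|a|,|b|)`), against plain-TSV concept and
   abbreviation dictionaries.

Entity-level strict evaluation (exact boundaries + type), token confusion
matrices, CoNLL-2003-style interchange, a seeded synthetic-corpus
generator, and a `clintagger` CLI (`synth`, `convert`, `train`, `predict`,
`evaluate`, `normalize`, `pipeline`, `validate`) tie the stages together.
It is aimed at researchers who need a controlled, dependency-light
implementation of this pipeline; licensed terminologies (SNOMED-CT,
abbreviation databases) are not shipped — any TSV of the same shape works.

## Worked example

```python
from clintagger import (PHARMA_TYPES, TagSchema, build_tagset, encode,
                        decode, normalize_mention, ConceptDictionary,
                        AbbreviationDictionary, EntityMention)
from clintagger.preprocess import tokenize

schema = TagSchema(PHARMA_TYPES)        # 4 types -> 21 tags
text = " " * 950 + ("instaurándose tratamiento con corticoides orales "
                    "en forma de prednisona oral")
tokens = tokenize(text)                 # document-level offsets
mentions = [EntityMention(980, 991, "NORMALIZABLES", "corticoides", "T1"),
            EntityMention(1011, 1021, "NORMALIZABLES", "prednisona", "T2")]
seq = encode(tokens, mentions, schema)
back = decode(seq, schema, text=text)

dictionary = ConceptDictionary({"373757009": {"prednisona"},
                                "116601002": {"hemoglobina"}})
abbrevs = AbbreviationDictionary({"hb": "hemoglobina"})
normalize_mention("prednisena", dictionary, abbrevs)  # misspelled
normalize_mention("Hb", dictionary, abbrevs)          # abbreviated
```

prints (offsets, tags and concept links computed, not stored):

```
tag inventory: 21 tags
tokens: [('instaurándose', 950, 963), ('tratamiento', 964, 975), ('con', 976, 979), ('corticoides', 980, 991)] ...
tags:   ['O', 'O', 'O', 'W-NORMALIZABLES', 'O', 'O', 'O', 'O', 'W-NORMALIZABLES', 'O']
decoded: [('corticoides', 980, 991, 'NORMALIZABLES'), ('prednisona', 1011, 1021, 'NORMALIZABLES')]
'prednisena' -> 373757009 (stage=levenshtein, distance=1)
'Hb'         -> 116601002 (stage=exact)
```

The sentence tokenizes to the reference per-token offsets
(corticoides = 980–991, prednisona = 1011–1021), its gold tag sequence
decodes back to exactly the two drug mentions, a distance-1 misspelling is
recovered by the bounded Levenshtein stage, and an abbreviation is
expanded before exact lookup.

End-to-end from a shell:

```bash
clintagger synth --out corpus --n-docs 10 --seed 13 --nesting-rate 0.15
clintagger train --corpus corpus --model model.npz --seed 13
clintagger pipeline --corpus corpus --model model.npz \
    --dictionary corpus/dictionary.tsv \
    --abbreviations corpus/abbreviations.tsv --out out --json
```

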