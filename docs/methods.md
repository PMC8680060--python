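# Methods

This note documents the models and procedures implemented in `clintagger`,
the assumptions behind them, and the design choices made where the design
was genuinely open.

## Problem setting

Clinical case reports mention drugs, chemical compounds and proteins whose
automatic recognition (NER) and linking to a terminology (concept
normalization) are the first steps of clinical information extraction.
Two properties of clinical text drive the design here: mentions *nest*
(a span like *calcio iónico corregido* contains the independently
annotated *calcio*), and surface forms are noisy (abbreviations,
misspellings), which breaks naive dictionary lookup.

## The BMEWO-V tag scheme

Mentions with character offsets are converted to one tag per token.
Besides the familiar positional prefixes — **B**egin, **M**iddle (inside),
**E**nd, **W**hole (single-token mention), **O**utside — the scheme adds a
**V** tag for tokens covered by *two or more* mentions, which lets a flat
tag sequence carry one level of nesting. For `T` entity types the
inventory has `5·T + 1` tags (21 for the four-type clinical schema).

The encoding/decoding convention (the original description names the tag
but not its mechanics, so this is fixed here):

* **encode** — a token under exactly one mention gets W or B/M/E by
  position; a token under several mentions gets `V-<type>` of the
  *innermost* (shortest) covering mention; ties break on (length, start,
  type).
* **decode** — a maximal B…E run yields its enclosing mention; every V
  token inside a run additionally yields a single-token mention of the V
  tag's type. V may stand in for B or E at a run edge (outer mention whose
  nested token is first or last), and a V adjacent to no run is a
  standalone single-token mention.

**Limitation.** Only nestings whose inner mention is a single token
round-trip exactly; a multi-token inner mention collapses to per-token
V readings. The synthetic generator therefore only emits the recoverable
pattern, and the round-trip property test is exact on it.

`repair` deterministically rewrites raw model output into a well-formed
sequence (orphan M/E promoted to B-runs or W; mid-run type changes close
the previous run). It is idempotent and the identity on well-formed input.

## Text preprocessing

Sentence splitting and tokenization are deliberately rule-based and
deterministic rather than delegated to a statistical library: hyphenated
gene/protein names (``S-100``) and abbreviation-internal periods are known
error sources, so the behavior must be controlled and reproducible. Rules:
whitespace separation; every punctuation character is its own token;
hyphen splitting is on by default (configurable); a period between digits
stays inside a number; the sentence splitter protects a configurable
abbreviation list (``Dr.``, ``fig.``, …) and splits only before an
uppercase/digit/opening-bracket continuation. Offsets are 0-based,
end-exclusive unicode code points throughout; every token satisfies
`text[start:end] == token.text` by construction.

`normalize_corpus_text` (for building embedding corpora) lowercases,
strips punctuation, collapses whitespace and removes stopwords, in that
order; it is idempotent. Small Spanish/English stopword lists ship with
the package; any one-term-per-line file can be substituted.

The suffix-based POS tagger is a *testing placeholder* so that
sense-embedding lookup (`token|POS`) can be exercised; it makes no
linguistic claim and any external tagger can be plugged in.

## The Bi-LSTM-CRF tagger

Per sentence: (1) a character-level Bi-LSTM (25-dim character embeddings,
25 hidden units per direction) encodes each token's spelling into the
concatenated final states of both directions (50 dims) — this reconciles
the two stated character-feature sizes (a 25-feature character vector, a
50-dim character representation per token); (2) that feature is
concatenated with a 300-dim word embedding and a 128-dim sense embedding
(keyed `token|POS`, falling back to the bare token, then to the OOV
policy); (3) a word-level Bi-LSTM (100 units per direction) and a linear
layer produce per-tag emission scores; (4) a linear-chain CRF with virtual
START/STOP states defines the objective.

Training minimizes the negative path log-likelihood `logZ − score(gold)`
by per-sentence SGD (learning rate 0.005, 100 epochs, dropout 0.5 applied
to the assembled feature vectors during training only). `logZ` comes from
the forward recursion in log space; gradients are the standard
forward–backward expected counts minus observed counts, propagated by
hand-derived backprop through every layer and verified against central
differences (≤1e-4 relative) in the test suite. All randomness flows from
one seeded generator, so training is bit-reproducible on one CPU thread.

Numerical/design choices:

* **Transition masking** (default on): structurally impossible BMEWO-V
  transitions (O→M, B-t₁→E-t₂, B→STOP, …) are held at −10⁴ rather than
  −∞ so the log-space recursions stay NaN-free; V transitions are
  unconstrained on both sides because a V tag's type is the *inner*
  mention's and is independent of the outer run. Every gold encoding is
  mask-admissible (property-tested).
* **Gradient clipping at global norm 25** guards the NaN-abort path
  without throttling learning: measured per-sentence gradient norms on the
  default synthetic task have median ≈ 10 (p90 ≈ 17), so a cap of 5 would
  rescale ~85 % of updates — an accidental learning-rate reduction that
  measurably prevents convergence within the 100-epoch budget — while a
  cap of 25 engages only on outliers.
* **OOV policy**: zero vector for frozen pre-trained tables (consistent
  with out-of-vocabulary words being a known recall limiter), a trainable
  UNK row for randomly initialized tables.
* **Mini-batch size 1** (per-sentence SGD); Viterbi ties break toward the
  lowest tag index, making decoding deterministic.
* Optional early stopping (validation loss, configurable patience) is off
  by default.
* Models serialize to a single `.npz` archive with an embedded format
  version, config, vocabularies and schema.

Pre-trained embeddings load from whitespace-delimited text (optional
`count dim` header, gzip-transparent); random initialization is the
default and is what the tests use.

## Evaluation

Entity-level scoring is strict: a prediction is a true positive iff its
(start, end, type) triple exactly matches a gold mention, matched
one-to-one; duplicate predicted triples count once (deduplication on, as
in common NER evaluators); nested gold mentions are scored independently.
P/R/F1 are percentages; a zero denominator reports 0 with an `undefined`
flag. Token-level confusion matrices collapse tag prefixes to entity
types (V to the V tag's type) plus O.

## Concept normalization

The two-stage dictionary search, per mention: lowercase → whole-token
abbreviation expansion (greedy, longest key first) → exact term lookup →
minimal Levenshtein distance match under `max_edit_distance` (default 1)
→ fuzzy match by normalized similarity `1 − d/max(|a|,|b|)` against a
threshold (default 0.80) → unmatched. The fuzzy threshold value and the
similarity formula are this package's choices (the approach is named in
the source description but not parameterized); both are configuration.
Ambiguous terms resolve to the lexicographically smallest concept id with
an ambiguity flag (policy `reject` available). The edit distance is the
classic two-row dynamic program, property-tested for identity, symmetry
and the triangle inequality and checked against an independent alignment
library on random pairs.

`conceptize_text` applies the dictionary to running text (non-overlapping,
longest-match-first, left-to-right, on whitespace-token boundaries) — the
transform used to build concept-level embedding corpora. Dictionaries are
plain TSV (`concept_id<TAB>term`; `abbrev<TAB>expansion`); SNOMED-CT and
the Spanish abbreviation databases are licensed resources and are not
shipped — any dictionary of the same shape drops in.

## Synthetic corpus generator

The generator emulates what the pipeline needs from a clinical NER corpus
and nothing more: short templated Spanish-like carrier sentences with
embedded dictionary terms as mentions. Controlled features: entity types
(default the four-type clinical schema), mentions per sentence
(mean `mention_rate`, at most two per sentence), nesting (inner
single-token mention), abbreviated surfaces, and misspelled surfaces at an
*exact* target edit distance (verified by computation, re-drawn on
collapse; edits never touch token-separating spaces).

Choices worth noting:

* Dictionary terms are pronounceable CV-syllable words, rejection-sampled
  to pairwise Levenshtein distance ≥ `max(3, 2·misspelling_distance + 1)`
  so each perturbed surface has a unique nearest term — this is what makes
  the normalization-recovery experiment a theorem rather than a tendency.
  For the opposite experiment (misspellings beyond both search bounds must
  stay unmatched) the separation is raised to 9 and term length capped at
  14 characters, which makes `similarity < 0.80` provable against every
  dictionary term.
* Whether a concept is nested-annotated, and the inner mention's type,
  are decided *once per corpus* — not per occurrence — so identical
  surface strings carry consistent labels, as real annotation guidelines
  require; per-occurrence draws would inject label noise that no model
  could fit.
* Default training-corpus size is 10 documents × 5 sentences = 50
  sentences, small enough that the full training-recovery experiment runs
  in minutes on one CPU while still covering all four entity types,
  multi-token mentions and nesting.

What passing tests on this generator do **not** show: robustness to real
tokenization noise, real class imbalance, discontinuous or multi-token
inner nested mentions, or generalization beyond the training vocabulary —
the recovery experiments are *capacity and correctness* checks (can the
implementation fit what it is defined to fit, and are the codecs exact
inverses), not benchmark claims.

## Known limitations

* One nesting level, inner mention restricted to a single token at decode
  time (encoding accepts arbitrary overlaps).
* Discontinuous BRAT fragment spans are rejected, not merged.
* The CRF is first-order; no transformer/contextual encoder is included.
* Dictionary search is whole-string; no token-level full-text index.
* The numpy implementation is single-threaded; it targets desk-scale
  corpora, not the original multi-hundred-megabyte embedding setups.
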