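"""Hybrid character + word + sense Bi-LSTM-CRF sequence tagger.

Architecture (per sentence):

1. every token's characters are embedded (``char_dim`` features each) and
   run through a character-level Bi-LSTM; the concatenated final states of
   both directions (``2·char_hidden``) form the token's morphological
   feature;
2. that feature is concatenated with the token's word embedding and its
   sense embedding (looked up by ``token|POS`` with fallback to the bare
   token), dropout is applied during training;
3. a word-level Bi-LSTM encodes the sentence and a linear layer produces
   per-tag emission scores;
4. a linear-chain CRF with (optionally masked) transition parameters
   defines the training objective ``logZ - score(gold)`` and Viterbi
   decoding at prediction time.

Training is per-sentence stochastic gradient descent with global-norm
gradient clipping; all gradients are hand-derived and checked numerically
in the test suite.  With a fixed seed on one CPU thread, training is
bit-reproducible.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from . import crf as crf_mod
from .codec import TagSchema, TagSequence, repair
from .layers import (
    BiLSTM,
    Embedding,
    Linear,
    clip_gradients,
    dropout_mask,
    uniform_init,
)
from .preprocess import Token, suffix_pos_tag

logger = logging.getLogger(__name__)

__all__ = ["TaggerConfig", "EmbeddingTable", "NeuralTagger", "load_embedding_text"]

UNK = "<UNK>"
FORMAT_VERSION = "clintagger-model-1"


@dataclass
class TaggerConfig:
    """Hyperparameters; defaults follow the reference configuration
    (SGD, learning rate 0.005, dropout 0.5, 100 epochs, 300-dim word and
    128-dim sense embeddings, 100 hidden units per LSTM direction, and a
    25-dim character embedding whose bidirectional encoder output is 50)."""

    char_dim: int = 25
    char_hidden: int = 25
    word_dim: int = 300
    sense_dim: int = 128
    lstm_hidden: int = 100
    dropout: float = 0.5
    learning_rate: float = 0.005
    optimizer: str = "sgd"
    epochs: int = 100
    seed: int = 0
    gradient_clip: float = 25.0
    mask_transitions: bool = True
    patience: Optional[int] = None  # early stopping on a validation set, off by default

    def __post_init__(self):
        for name in ("char_dim", "char_hidden", "word_dim", "sense_dim", "lstm_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.optimizer != "sgd":
            raise ValueError("only stochastic gradient descent is implemented")


@dataclass
class EmbeddingTable:
    """A token→vector lookup with a total OOV policy.

    ``oov_policy``: ``"zero"`` (OOV maps to the zero vector, the usual
    choice for frozen pre-trained tables), ``"random-seeded"`` (a fixed
    random vector drawn from the table's seed), or ``"trainable-unk"``
    (OOV shares a trainable UNK row — the default for randomly initialized
    tables).
    """

    vocabulary: dict[str, int]
    vectors: np.ndarray
    oov_policy: str = "trainable-unk"
    trainable: bool = True

    def __post_init__(self):
        if self.oov_policy not in ("zero", "random-seeded", "trainable-unk"):
            raise ValueError(f"unknown oov_policy {self.oov_policy!r}")
        if self.oov_policy in ("zero", "random-seeded") and UNK in self.vocabulary:
            pass
        if self.oov_policy == "trainable-unk" and UNK not in self.vocabulary:
            raise ValueError("trainable-unk policy requires an <UNK> row")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @classmethod
    def random(
        cls,
        tokens: Iterable[str],
        dim: int,
        rng: np.random.Generator,
        trainable: bool = True,
    ) -> "EmbeddingTable":
        vocab = {UNK: 0}
        for tok in tokens:
            vocab.setdefault(tok, len(vocab))
        vectors = uniform_init(rng, (len(vocab), dim), scale=np.sqrt(3.0 / dim))
        return cls(vocab, vectors, oov_policy="trainable-unk", trainable=trainable)

    def index(self, token: str) -> int:
        idx = self.vocabulary.get(token)
        if idx is not None:
            return idx
        if self.oov_policy == "trainable-unk":
            return self.vocabulary[UNK]
        return -1  # resolved by lookup()

    def lookup(self, token: str) -> np.ndarray:
        idx = self.index(token)
        if idx >= 0:
            return self.vectors[idx]
        if self.oov_policy == "zero":
            return np.zeros(self.dim)
        rng = np.random.default_rng(abs(hash(token)) % (2 ** 31))
        return rng.uniform(-0.1, 0.1, self.dim)


def load_embedding_text(
    path: str | Path, oov_policy: str = "zero", trainable: bool = False
) -> EmbeddingTable:
    """Load whitespace-delimited text vectors (word2vec ``.txt`` layout).

    An optional first line ``<count> <dim>`` is recognized and skipped;
    ``.gz`` files are decompressed transparently.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []
    with opener(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
        parts = first.rstrip("\n").split(" ")
        if len(parts) != 2 or not all(p.isdigit() for p in parts):
            _add_embedding_row(parts, vocab, rows)
        for line in fh:
            _add_embedding_row(line.rstrip("\n").split(" "), vocab, rows)
    if not rows:
        raise ValueError(f"no vectors found in {path}")
    vectors = np.vstack(rows)
    if oov_policy == "trainable-unk" and UNK not in vocab:
        vocab[UNK] = len(vocab)
        vectors = np.vstack([vectors, np.zeros(vectors.shape[1])])
    return EmbeddingTable(vocab, vectors, oov_policy=oov_policy, trainable=trainable)


def _add_embedding_row(parts: list[str], vocab: dict, rows: list) -> None:
    if len(parts) < 2:
        return
    word = parts[0]
    vec = np.array([float(x) for x in parts[1:]])
    if rows and vec.shape[0] != rows[0].shape[0]:
        raise ValueError(f"inconsistent vector dimension for {word!r}")
    if word not in vocab:
        vocab[word] = len(vocab)
        rows.append(vec)


def sense_key(token: str, pos: Optional[str]) -> str:
    return f"{token}|{pos}" if pos else token


class NeuralTagger:
    """The trainable model.  Build with :meth:`build`, train with
    :meth:`fit`, decode with :meth:`predict`."""

    def __init__(
        self,
        schema: TagSchema,
        config: TaggerConfig,
        word_table: EmbeddingTable,
        sense_table: EmbeddingTable,
        char_vocab: dict[str, int],
    ):
        self.schema = schema
        self.config = config
        self.word_table = word_table
        self.sense_table = sense_table
        self.char_vocab = char_vocab
        self.rng = np.random.default_rng(config.seed)
        K = len(schema)
        feat_dim = word_table.dim + sense_table.dim + 2 * config.char_hidden

        self.char_emb = Embedding.create(self.rng, len(char_vocab), config.char_dim)
        self.char_lstm = BiLSTM.create(self.rng, config.char_dim, config.char_hidden)
        self.word_lstm = BiLSTM.create(self.rng, feat_dim, config.lstm_hidden)
        self.out = Linear.create(self.rng, 2 * config.lstm_hidden, K)
        self.transitions = uniform_init(self.rng, (K + 2, K + 2), scale=0.1)
        self.mask = (
            crf_mod.build_transition_mask(schema)
            if config.mask_transitions
            else np.ones((K + 2, K + 2), dtype=bool)
        )

    # -- construction -------------------------------------------------

    @classmethod
    def build(
        cls,
        schema: TagSchema,
        corpus: Sequence[TagSequence],
        config: Optional[TaggerConfig] = None,
        word_table: Optional[EmbeddingTable] = None,
        sense_table: Optional[EmbeddingTable] = None,
        pos_tagger=suffix_pos_tag,
    ) -> "NeuralTagger":
        """Create a model whose vocabularies cover ``corpus``; tables not
        supplied are randomly initialized (and trainable)."""
        config = config or TaggerConfig()
        rng = np.random.default_rng(config.seed)
        words: list[str] = []
        senses: list[str] = []
        chars: dict[str, int] = {UNK: 0}
        for seq in corpus:
            for tok in seq.tokens:
                words.append(tok.text)
                pos = tok.pos_tag or (pos_tagger(tok.text) if pos_tagger else None)
                senses.append(sense_key(tok.text, pos))
                senses.append(tok.text)
                for ch in tok.text:
                    chars.setdefault(ch, len(chars))
        if word_table is None:
            word_table = EmbeddingTable.random(sorted(set(words)), config.word_dim, rng)
        if sense_table is None:
            sense_table = EmbeddingTable.random(sorted(set(senses)), config.sense_dim, rng)
        model = cls(schema, config, word_table, sense_table, chars)
        model.pos_tagger = pos_tagger
        return model

    pos_tagger = staticmethod(suffix_pos_tag)

    # -- feature assembly ---------------------------------------------

    def _char_indices(self, tokens: Sequence[Token]) -> tuple[np.ndarray, np.ndarray]:
        lengths = np.array([max(1, len(t.text)) for t in tokens], dtype=np.intp)
        T = int(lengths.max())
        idx = np.zeros((T, len(tokens)), dtype=np.intp)
        for b, tok in enumerate(tokens):
            for j, ch in enumerate(tok.text):
                idx[j, b] = self.char_vocab.get(ch, self.char_vocab[UNK])
        return idx, lengths

    def _sense_index(self, tok: Token) -> int:
        pos = tok.pos_tag or (self.pos_tagger(tok.text) if self.pos_tagger else None)
        key = sense_key(tok.text, pos)
        if key in self.sense_table.vocabulary:
            return self.sense_table.vocabulary[key]
        if tok.text in self.sense_table.vocabulary:
            return self.sense_table.vocabulary[tok.text]
        return self.sense_table.index(tok.text)

    def char_encode(self, token_text: str) -> np.ndarray:
        """Character feature of one token (2·char_hidden,); deterministic."""
        if not token_text:
            raise ValueError("token must be non-empty")
        tok = Token(token_text, 0, len(token_text))
        idx, lengths = self._char_indices([tok])
        emb = self.char_emb.forward(idx)
        Hs, _ = self.char_lstm.forward(emb, lengths)
        return self.char_lstm.final_states(Hs, lengths)[0]

    def assemble_features(self, tokens: Sequence[Token]) -> np.ndarray:
        """(L, word_dim + sense_dim + 2·char_hidden) feature matrix."""
        feats, _ = self._features_forward(tokens)
        return feats

    def _features_forward(self, tokens: Sequence[Token]):
        word_idx = np.array([self.word_table.index(t.text) for t in tokens], dtype=np.intp)
        word_vecs = np.array([
            self.word_table.vectors[i] if i >= 0 else self.word_table.lookup(t.text)
            for i, t in zip(word_idx, tokens)
        ])
        sense_idx = np.array([self._sense_index(t) for t in tokens], dtype=np.intp)
        sense_vecs = np.array([
            self.sense_table.vectors[i] if i >= 0 else self.sense_table.lookup(t.text)
            for i, t in zip(sense_idx, tokens)
        ])
        cidx, clens = self._char_indices(tokens)
        cemb = self.char_emb.forward(cidx)
        cHs, c_cache = self.char_lstm.forward(cemb, clens)
        char_feats = self.char_lstm.final_states(cHs, clens)
        feats = np.concatenate([word_vecs, sense_vecs, char_feats], axis=1)
        cache = {
            "word_idx": word_idx, "sense_idx": sense_idx,
            "cidx": cidx, "clens": clens, "c_cache": c_cache,
            "cHs_shape": cHs.shape,
        }
        return feats, cache

    def _forward(self, tokens: Sequence[Token], train: bool):
        feats, fcache = self._features_forward(tokens)
        if train and self.config.dropout > 0:
            mask = dropout_mask(self.rng, feats.shape, self.config.dropout)
            feats = feats * mask
            fcache["dropout"] = mask
        X = feats[:, None, :]  # (L, 1, D)
        Hs, lstm_cache = self.word_lstm.forward(X)
        em, lin_cache = self.out.forward(Hs[:, 0, :])
        transitions = crf_mod.apply_mask(self.transitions, self.mask)
        return em, transitions, (fcache, lstm_cache, lin_cache)

    # -- loss and gradients -------------------------------------------

    def _loss_and_grads(self, seq: TagSequence, train: bool = True):
        tokens = seq.tokens
        gold = [self.schema.tag_to_index[t] for t in seq.tags]
        em, transitions, (fcache, lstm_cache, lin_cache) = self._forward(tokens, train)
        unary, pairwise, logZ = crf_mod.crf_marginals(em, transitions)
        gold_score = crf_mod.crf_score(em, transitions, gold)
        loss = logZ - gold_score

        L, K = em.shape
        d_em = unary.copy()
        d_em[np.arange(L), gold] -= 1.0
        d_trans = pairwise
        start, stop = K, K + 1
        d_trans[start, gold[0]] -= 1.0
        d_trans[gold[-1], stop] -= 1.0
        for i in range(1, L):
            d_trans[gold[i - 1], gold[i]] -= 1.0
        d_trans = d_trans * self.mask  # masked cells carry no gradient

        dH, lin_grads = self.out.backward(d_em, lin_cache)
        dX, lstm_grads = self.word_lstm.backward(dH[:, None, :], lstm_cache)
        dfeats = dX[:, 0, :]
        if "dropout" in fcache:
            dfeats = dfeats * fcache["dropout"]

        wd, sd = self.word_table.dim, self.sense_table.dim
        d_word = dfeats[:, :wd]
        d_sense = dfeats[:, wd:wd + sd]
        d_char = dfeats[:, wd + sd:]

        grads: dict = {
            "out": lin_grads,
            "word_lstm": lstm_grads,
            "transitions": d_trans,
        }
        dcHs = self.char_lstm.final_states_backward(
            d_char, fcache["cHs_shape"], fcache["clens"]
        )
        dcemb, char_lstm_grads = self.char_lstm.backward(dcHs, fcache["c_cache"])
        grads["char_lstm"] = char_lstm_grads
        grads["char_emb"] = self.char_emb.backward(fcache["cidx"], dcemb)
        if self.word_table.trainable:
            g = np.zeros_like(self.word_table.vectors)
            ok = fcache["word_idx"] >= 0
            np.add.at(g, fcache["word_idx"][ok], d_word[ok])
            grads["word_table"] = g
        if self.sense_table.trainable:
            g = np.zeros_like(self.sense_table.vectors)
            ok = fcache["sense_idx"] >= 0
            np.add.at(g, fcache["sense_idx"][ok], d_sense[ok])
            grads["sense_table"] = g
        return loss, grads

    def _apply_sgd(self, grads: dict) -> None:
        lr = self.config.learning_rate
        self.out.W -= lr * grads["out"]["W"]
        self.out.b -= lr * grads["out"]["b"]
        for name, lstm in (("word_lstm", self.word_lstm), ("char_lstm", self.char_lstm)):
            for direction in ("fwd", "bwd"):
                cell = getattr(lstm, direction)
                g = grads[name][direction]
                cell.W -= lr * g["W"]
                cell.U -= lr * g["U"]
                cell.b -= lr * g["b"]
        self.transitions -= lr * grads["transitions"]
        self.char_emb.table -= lr * grads["char_emb"]
        if "word_table" in grads:
            self.word_table.vectors -= lr * grads["word_table"]
        if "sense_table" in grads:
            self.sense_table.vectors -= lr * grads["sense_table"]

    # -- public API ----------------------------------------------------

    def fit(
        self,
        corpus: Sequence[TagSequence],
        epochs: Optional[int] = None,
        validation: Optional[Sequence[TagSequence]] = None,
        shuffle: bool = True,
        callback=None,
    ) -> list[float]:
        """Train by per-sentence SGD; returns mean training loss per epoch.

        With ``config.patience`` set and a validation corpus given, stops
        when validation loss has not improved for ``patience`` epochs.
        """
        if not corpus:
            raise ValueError("training corpus is empty")
        epochs = epochs if epochs is not None else self.config.epochs
        history: list[float] = []
        best_val = np.inf
        stale = 0
        order = np.arange(len(corpus))
        for epoch in range(epochs):
            if shuffle:
                self.rng.shuffle(order)
            total = 0.0
            for k in order:
                loss, grads = self._loss_and_grads(corpus[k], train=True)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, sentence {k}: {loss}"
                    )
                clip_gradients(grads, self.config.gradient_clip)
                self._apply_sgd(grads)
                total += loss
            mean_loss = total / len(corpus)
            history.append(mean_loss)
            logger.info("epoch %d: training loss %.4f", epoch + 1, mean_loss)
            if validation is not None and self.config.patience is not None:
                val = self.evaluate_loss(validation)
                if val < best_val - 1e-8:
                    best_val, stale = val, 0
                else:
                    stale += 1
                    if stale >= self.config.patience:
                        logger.info("early stop at epoch %d", epoch + 1)
                        break
            if callback is not None:
                callback(epoch, mean_loss)
        return history

    def evaluate_loss(self, corpus: Sequence[TagSequence]) -> float:
        return float(
            np.mean([self._loss_and_grads(seq, train=False)[0] for seq in corpus])
        )

    def predict(
        self, sentences: Sequence[Sequence[Token]], repair_output: bool = True
    ) -> list[TagSequence]:
        """Viterbi-decode tag sequences (dropout off, deterministic)."""
        out = []
        tags_list = self.schema.tags
        for tokens in sentences:
            tokens = list(tokens)
            if not tokens:
                out.append(TagSequence([], []))
                continue
            em, transitions, _ = self._forward(tokens, train=False)
            path, _score = crf_mod.viterbi_decode(em, transitions)
            raw = [tags_list[i] for i in path]
            if repair_output:
                out.append(TagSequence(tokens, repair(raw, self.schema)))
            else:
                out.append(TagSequence(tokens, raw, raw=True))
        return out

    # -- serialization -------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file archive: parameter arrays plus a JSON metadata
        record carrying the format version, config, schema and vocabularies."""
        meta = {
            "format_version": FORMAT_VERSION,
            "config": asdict(self.config),
            "entity_types": list(self.schema.entity_types),
            "word_vocab": self.word_table.vocabulary,
            "word_oov": self.word_table.oov_policy,
            "word_trainable": self.word_table.trainable,
            "sense_vocab": self.sense_table.vocabulary,
            "sense_oov": self.sense_table.oov_policy,
            "sense_trainable": self.sense_table.trainable,
            "char_vocab": self.char_vocab,
        }
        arrays = {
            "word_vectors": self.word_table.vectors,
            "sense_vectors": self.sense_table.vectors,
            "char_emb": self.char_emb.table,
            "out_W": self.out.W,
            "out_b": self.out.b,
            "transitions": self.transitions,
            "meta": np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
        }
        for name, lstm in (("word", self.word_lstm), ("char", self.char_lstm)):
            for direction in ("fwd", "bwd"):
                cell = getattr(lstm, direction)
                arrays[f"{name}_{direction}_W"] = cell.W
                arrays[f"{name}_{direction}_U"] = cell.U
                arrays[f"{name}_{direction}_b"] = cell.b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "NeuralTagger":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
            if meta.get("format_version") != FORMAT_VERSION:
                raise ValueError(
                    f"unsupported model format {meta.get('format_version')!r}"
                )
            config = TaggerConfig(**meta["config"])
            schema = TagSchema(tuple(meta["entity_types"]))
            word = EmbeddingTable(
                meta["word_vocab"], data["word_vectors"],
                meta["word_oov"], meta["word_trainable"],
            )
            sense = EmbeddingTable(
                meta["sense_vocab"], data["sense_vectors"],
                meta["sense_oov"], meta["sense_trainable"],
            )
            model = cls(schema, config, word, sense, meta["char_vocab"])
            model.char_emb.table = data["char_emb"].copy()
            model.out.W = data["out_W"].copy()
            model.out.b = data["out_b"].copy()
            model.transitions = data["transitions"].copy()
            for name, lstm in (("word", model.word_lstm), ("char", model.char_lstm)):
                for direction in ("fwd", "bwd"):
                    cell = getattr(lstm, direction)
                    cell.W = data[f"{name}_{direction}_W"].copy()
                    cell.U = data[f"{name}_{direction}_U"].copy()
                    cell.b = data[f"{name}_{direction}_b"].copy()
        return model
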