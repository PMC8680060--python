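"""The Bi-LSTM-CRF tagger: feature assembly, gradients, training, I/O."""

import numpy as np
import pytest

from clintagger import TagSchema, TagSequence, Token
from clintagger.tagger import (
    UNK,
    EmbeddingTable,
    NeuralTagger,
    TaggerConfig,
    load_embedding_text,
    sense_key,
)

TINY = dict(char_dim=4, char_hidden=4, word_dim=8, sense_dim=6, lstm_hidden=6)


def toks(*texts):
    out, pos = [], 0
    for t in texts:
        out.append(Token(t, pos, pos + len(t)))
        pos += len(t) + 1
    return out


@pytest.fixture
def schema():
    return TagSchema(("DRUG", "PROT"))


@pytest.fixture
def tiny_corpus(schema):
    return [
        TagSequence(toks("se", "pauta", "amoxicilina"), ["O", "O", "W-DRUG"]),
        TagSequence(toks("control", "de", "hemoglobina"), ["O", "O", "W-PROT"]),
        TagSequence(
            toks("recibe", "acido", "valproico", "oral"),
            ["O", "B-DRUG", "E-DRUG", "O"],
        ),
    ]


@pytest.fixture
def tiny_model(schema, tiny_corpus):
    cfg = TaggerConfig(dropout=0.0, seed=3, **TINY)
    return NeuralTagger.build(schema, tiny_corpus, cfg)


class TestConfig:
    def test_defaults_match_reference_settings(self):
        cfg = TaggerConfig()
        assert cfg.char_dim == 25
        assert cfg.char_hidden == 25  # bidirectional char feature = 50
        assert cfg.word_dim == 300
        assert cfg.sense_dim == 128
        assert cfg.lstm_hidden == 100
        assert cfg.dropout == 0.5
        assert cfg.learning_rate == 0.005
        assert cfg.epochs == 100
        assert cfg.optimizer == "sgd"

    @pytest.mark.parametrize("bad", [{"dropout": 1.0}, {"word_dim": 0},
                                     {"optimizer": "adam"}])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            TaggerConfig(**bad)


class TestEmbeddingTable:
    def test_known_token_returns_table_row(self):
        rng = np.random.default_rng(0)
        table = EmbeddingTable.random(["alfa", "beta"], 5, rng)
        idx = table.vocabulary["alfa"]
        np.testing.assert_array_equal(table.lookup("alfa"), table.vectors[idx])

    def test_zero_policy_gives_zero_vector(self):
        table = EmbeddingTable({"a": 0}, np.ones((1, 4)), oov_policy="zero")
        np.testing.assert_array_equal(table.lookup("missing"), 0.0)

    def test_trainable_unk_shares_row(self):
        rng = np.random.default_rng(1)
        table = EmbeddingTable.random(["a"], 4, rng)
        np.testing.assert_array_equal(
            table.lookup("missing"), table.vectors[table.vocabulary[UNK]]
        )

    def test_loader_reads_text_vectors(self, tmp_path):
        path = tmp_path / "vecs.txt"
        path.write_text("2 3\nalfa 1.0 2.0 3.0\nbeta 0.5 0.5 0.5\n")
        table = load_embedding_text(path)
        assert table.dim == 3
        np.testing.assert_array_equal(table.lookup("alfa"), [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(table.lookup("zzz"), 0.0)

    def test_loader_without_header(self, tmp_path):
        path = tmp_path / "vecs.txt"
        path.write_text("alfa 1.0 2.0\nbeta 3.0 4.0\n")
        table = load_embedding_text(path)
        assert len(table.vocabulary) == 2
        assert table.dim == 2

    def test_loader_gzip(self, tmp_path):
        import gzip

        path = tmp_path / "vecs.txt.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("alfa 1.0 2.0\n")
        assert load_embedding_text(path).dim == 2


class TestCharEncoder:
    def test_deterministic(self, tiny_model):
        a = tiny_model.char_encode("Hb")
        b = tiny_model.char_encode("Hb")
        np.testing.assert_array_equal(a, b)

    def test_case_sensitive(self, tiny_model):
        assert not np.allclose(tiny_model.char_encode("Hb"), tiny_model.char_encode("hb"))

    def test_output_dimension(self, tiny_model):
        assert tiny_model.char_encode("amoxicilina").shape == (2 * TINY["char_hidden"],)

    def test_zero_weights_zero_feature(self, schema, tiny_corpus):
        m = NeuralTagger.build(
            schema, tiny_corpus, TaggerConfig(dropout=0.0, seed=0, **TINY)
        )
        for cell in (m.char_lstm.fwd, m.char_lstm.bwd):
            cell.W[:] = 0.0
            cell.U[:] = 0.0
            cell.b[:] = 0.0
        np.testing.assert_array_equal(m.char_encode("anything"), 0.0)

    def test_empty_token_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.char_encode("")


class TestAssembleFeatures:
    def test_dimension(self, tiny_model):
        feats = tiny_model.assemble_features(toks("se", "pauta"))
        assert feats.shape == (2, TINY["word_dim"] + TINY["sense_dim"] + 2 * TINY["char_hidden"])

    def test_known_word_block_is_table_row(self, tiny_model):
        feats = tiny_model.assemble_features(toks("pauta"))
        idx = tiny_model.word_table.vocabulary["pauta"]
        np.testing.assert_array_equal(
            feats[0, : TINY["word_dim"]], tiny_model.word_table.vectors[idx]
        )

    def test_oov_word_zero_policy(self, schema, tiny_corpus):
        cfg = TaggerConfig(dropout=0.0, seed=3, **TINY)
        model = NeuralTagger.build(schema, tiny_corpus, cfg)
        model.word_table.oov_policy = "zero"
        model.word_table.vocabulary.pop(UNK, None)
        feats = model.assemble_features(toks("zzzznuevo"))
        np.testing.assert_array_equal(feats[0, : TINY["word_dim"]], 0.0)

    def test_sense_lookup_prefers_pos_key_then_token(self, tiny_model):
        tok = Token("oral", 0, 4, pos_tag="ADJ")
        key = sense_key("oral", "ADJ")
        vocab = tiny_model.sense_table.vocabulary
        # with the pos key present it is used
        vocab[key] = vocab[UNK]
        assert tiny_model._sense_index(tok) == vocab[key]
        # without it, fall back to the bare token
        del vocab[key]
        vocab["oral"] = 1
        assert tiny_model._sense_index(tok) == 1


class TestTraining:
    def test_loss_decreases_without_dropout(self, schema, tiny_corpus):
        cfg = TaggerConfig(dropout=0.0, seed=5, learning_rate=0.005, **TINY)
        model = NeuralTagger.build(schema, tiny_corpus, cfg)
        history = model.fit(tiny_corpus, epochs=30, shuffle=False)
        assert history[-1] < history[0]
        # per-epoch deterministic objective is (weakly) non-increasing
        assert all(b <= a + 1e-6 for a, b in zip(history, history[1:]))

    def test_memorizes_single_sentence(self, schema):
        """A one-sentence corpus is memorized within 200 epochs at the
        default hyperparameters."""
        seq = TagSequence(
            toks("se", "pauta", "amoxicilina", "oral"), ["O", "O", "W-DRUG", "O"]
        )
        model = NeuralTagger.build(schema, [seq], TaggerConfig(seed=7))
        model.fit([seq], epochs=200)
        pred = model.predict([seq.tokens])[0]
        assert pred.tags == seq.tags

    def test_training_is_deterministic(self, schema, tiny_corpus):
        losses = []
        for _ in range(2):
            cfg = TaggerConfig(dropout=0.5, seed=11, **TINY)
            model = NeuralTagger.build(schema, tiny_corpus, cfg)
            losses.append(model.fit(tiny_corpus, epochs=5))
        assert losses[0] == losses[1]

    def test_empty_corpus_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.fit([])

    def test_gradient_check_end_to_end(self, schema, tiny_corpus):
        """Analytic gradient of the CRF negative log-likelihood agrees with
        central differences through the full network."""
        cfg = TaggerConfig(dropout=0.0, seed=13, **TINY)
        model = NeuralTagger.build(schema, tiny_corpus, cfg)
        seq = tiny_corpus[2]
        loss0, grads = model._loss_and_grads(seq, train=False)
        eps = 1e-6
        checks = [
            (model.out.W, grads["out"]["W"], (3, 2)),
            (model.word_lstm.fwd.W, grads["word_lstm"]["fwd"]["W"], (1, 4)),
            (model.word_lstm.bwd.U, grads["word_lstm"]["bwd"]["U"], (2, 9)),
            (model.char_lstm.fwd.W, grads["char_lstm"]["fwd"]["W"], (0, 3)),
            (model.char_emb.table, grads["char_emb"], (2, 1)),
            (model.word_table.vectors, grads["word_table"], (1, 3)),
            (model.transitions, grads["transitions"], (len(schema), 0)),
        ]
        for arr, grad, idx in checks:
            old = arr[idx]
            arr[idx] = old + eps
            up = model._loss_and_grads(seq, train=False)[0]
            arr[idx] = old - eps
            down = model._loss_and_grads(seq, train=False)[0]
            arr[idx] = old
            numeric = (up - down) / (2 * eps)
            denom = max(1e-8, abs(numeric) + abs(grad[idx]))
            assert abs(numeric - grad[idx]) / denom < 1e-4


class TestPredict:
    def test_empty_input(self, tiny_model):
        assert tiny_model.predict([]) == []

    def test_output_length_and_inventory(self, tiny_model, schema, tiny_corpus):
        preds = tiny_model.predict([s.tokens for s in tiny_corpus])
        for seq, pred in zip(tiny_corpus, preds):
            assert len(pred.tags) == len(seq.tokens)
            assert set(pred.tags) <= set(schema.tags)

    def test_prediction_deterministic_despite_dropout_config(self, schema, tiny_corpus):
        cfg = TaggerConfig(dropout=0.5, seed=2, **TINY)
        model = NeuralTagger.build(schema, tiny_corpus, cfg)
        a = model.predict([tiny_corpus[0].tokens])[0]
        b = model.predict([tiny_corpus[0].tokens])[0]
        assert a.tags == b.tags

    def test_raw_output_flagged(self, tiny_model, tiny_corpus):
        raw = tiny_model.predict([tiny_corpus[0].tokens], repair_output=False)[0]
        assert raw.raw


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, tiny_model, tiny_corpus):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        again = NeuralTagger.load(path)
        for seq in tiny_corpus:
            assert (
                tiny_model.predict([seq.tokens])[0].tags
                == again.predict([seq.tokens])[0].tags
            )

    def test_version_string_checked(self, tmp_path, tiny_model):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        import json

        import numpy as np

        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(bytes(arrays["meta"]).decode())
        meta["format_version"] = "bogus-9"
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        with pytest.raises(ValueError, match="format"):
            NeuralTagger.load(path)
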