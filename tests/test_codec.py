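"""BMEWO-V encoding, decoding, repair, and CoNLL interchange."""

import pytest

from clintagger import (
    PHARMA_TYPES,
    TagSchema,
    TagSequence,
    Token,
    build_tagset,
    decode,
    encode,
    from_conll,
    is_well_formed,
    repair,
    to_conll,
)
from clintagger.codec import MisalignedMentionError, to_bio
from clintagger.preprocess import tokenize
from clintagger.standoff import EntityMention

from .conftest import GOLD_TAGS_950, SENTENCE_950, SENTENCE_950_OFFSET


class TestBuildTagset:
    @pytest.mark.parametrize(
        "types,expected_size",
        [
            (PHARMA_TYPES, 21),
            (("DRUG",), 6),
            (("disorder", "chemical_or_drug", "protein_or_gene"), 16),
        ],
    )
    def test_inventory_size(self, types, expected_size):
        tags = build_tagset(types)
        assert len(tags) == expected_size == 5 * len(types) + 1

    def test_order_is_deterministic(self):
        tags = build_tagset(("A", "B"))
        assert tags == (
            "B-A", "M-A", "E-A", "W-A", "V-A",
            "B-B", "M-B", "E-B", "W-B", "V-B", "O",
        )

    def test_duplicate_type_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_tagset(("A", "A"))


def _sentence_950_tokens():
    text = " " * SENTENCE_950_OFFSET + SENTENCE_950
    return text, tokenize(text)


class TestEncode:
    def test_worked_example_single_token_mentions(self, pharma_schema):
        text, tokens = _sentence_950_tokens()
        mentions = [
            EntityMention(980, 991, "NORMALIZABLES", "corticoides", "T1"),
            EntityMention(1011, 1021, "NORMALIZABLES", "prednisona", "T2"),
        ]
        seq = encode(tokens, mentions, pharma_schema)
        assert seq.tags == GOLD_TAGS_950

    def test_no_mentions_all_outside(self, pharma_schema):
        _, tokens = _sentence_950_tokens()
        assert encode(tokens, [], pharma_schema).tags == ["O"] * len(tokens)

    def test_nested_single_token_inner(self, pharma_schema, nested_doc):
        tokens = tokenize(nested_doc.text)
        seq = encode(tokens, nested_doc.mentions, pharma_schema)
        assert seq.tags == ["V-NORMALIZABLES", "M-NORMALIZABLES", "E-NORMALIZABLES"]

    def test_multi_token_mention_bme(self, pharma_schema):
        tokens = tokenize("alfa feto proteina total")
        m = EntityMention(0, 18, "PROTEINAS", "alfa feto proteina", "T1")
        seq = encode(tokens, [m], pharma_schema)
        assert seq.tags == ["B-PROTEINAS", "M-PROTEINAS", "E-PROTEINAS", "O"]

    def test_misaligned_mention_raises(self, pharma_schema):
        tokens = tokenize("corticoides orales")
        m = EntityMention(0, 6, "NORMALIZABLES", "cortic", "T1")
        with pytest.raises(MisalignedMentionError):
            encode(tokens, [m], pharma_schema)

    def test_misaligned_mention_snaps_with_config(self, pharma_schema):
        tokens = tokenize("corticoides orales")
        m = EntityMention(0, 6, "NORMALIZABLES", "cortic", "T1")
        seq = encode(tokens, [m], pharma_schema, misalignment="snap-and-warn")
        assert seq.tags == ["W-NORMALIZABLES", "O"]

    def test_tags_always_in_inventory(self, pharma_schema, small_corpus):
        inventory = set(pharma_schema.tags)
        for ts in small_corpus.sentences:
            assert set(ts.sequence.tags) <= inventory


class TestDecode:
    def test_worked_example_two_drugs(self, pharma_schema):
        """Decoding the gold tags of the reference sentence yields exactly
        the two drug mentions at their printed offsets."""
        text, tokens = _sentence_950_tokens()
        seq = TagSequence(tokens, list(GOLD_TAGS_950))
        mentions = decode(seq, pharma_schema, text=text)
        assert [(m.start, m.end, m.entity_type) for m in mentions] == [
            (980, 991, "NORMALIZABLES"),
            (1011, 1021, "NORMALIZABLES"),
        ]

    def test_all_outside_empty(self, pharma_schema):
        _, tokens = _sentence_950_tokens()
        seq = TagSequence(tokens, ["O"] * len(tokens))
        assert decode(seq, pharma_schema) == []

    def test_v_run_yields_outer_plus_inner(self, pharma_schema, nested_doc):
        tokens = tokenize(nested_doc.text)
        seq = TagSequence(
            tokens, ["V-NORMALIZABLES", "M-NORMALIZABLES", "E-NORMALIZABLES"]
        )
        mentions = decode(seq, pharma_schema, text=nested_doc.text)
        assert {(m.start, m.end) for m in mentions} == {(0, 6), (0, 23)}

    def test_inner_type_may_differ_from_outer(self, pharma_schema):
        tokens = tokenize("calcio iónico corregido")
        seq = TagSequence(tokens, ["V-PROTEINAS", "M-UNCLEAR", "E-UNCLEAR"])
        mentions = decode(seq, pharma_schema)
        types = {(m.start, m.end): m.entity_type for m in mentions}
        assert types[(0, 6)] == "PROTEINAS"
        assert types[(0, 23)] == "UNCLEAR"

    def test_v_closing_a_run(self, pharma_schema):
        tokens = tokenize("acido urico")
        seq = TagSequence(tokens, ["B-NORMALIZABLES", "V-PROTEINAS"])
        mentions = decode(seq, pharma_schema)
        assert {(m.start, m.end, m.entity_type) for m in mentions} == {
            (0, 11, "NORMALIZABLES"),
            (6, 11, "PROTEINAS"),
        }

    def test_never_emits_empty_span(self, pharma_schema, small_corpus):
        for ts in small_corpus.sentences:
            for m in decode(ts.sequence, pharma_schema):
                assert m.start < m.end


class TestRoundTrip:
    def test_decode_encode_identity_on_generated_corpus(self, small_corpus, pharma_schema):
        """decode∘encode recovers the gold mention set for every sentence of
        a corpus whose overlaps follow the recoverable nesting pattern."""
        for ts in small_corpus.sentences:
            doc = next(
                d for d in small_corpus.documents if d.doc_id == ts.doc_id
            )
            got = decode(ts.sequence, pharma_schema, text=doc.text)
            s0 = ts.sequence.tokens[0].start
            e0 = ts.sequence.tokens[-1].end
            expected = {
                (m.start, m.end, m.entity_type)
                for m in doc.mentions
                if s0 <= m.start and m.end <= e0
            }
            assert {(m.start, m.end, m.entity_type) for m in got} == expected


class TestRepair:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (["M-UNCLEAR"], ["W-UNCLEAR"]),
            (["B-UNCLEAR", "O"], ["W-UNCLEAR", "O"]),
            (["E-UNCLEAR"], ["W-UNCLEAR"]),
            (["B-UNCLEAR", "M-UNCLEAR", "O"], ["B-UNCLEAR", "E-UNCLEAR", "O"]),
            (["B-UNCLEAR", "M-PROTEINAS", "E-PROTEINAS"],
             ["W-UNCLEAR", "B-PROTEINAS", "E-PROTEINAS"]),
            (["O", "M-PROTEINAS", "E-PROTEINAS"], ["O", "B-PROTEINAS", "E-PROTEINAS"]),
        ],
    )
    def test_repair_rules(self, pharma_schema, raw, expected):
        assert repair(raw, pharma_schema) == expected

    def test_well_formed_input_unchanged(self, pharma_schema, small_corpus):
        for ts in small_corpus.sentences:
            assert repair(ts.sequence.tags, pharma_schema) == ts.sequence.tags

    def test_idempotent(self, pharma_schema):
        raws = [
            ["M-UNCLEAR", "E-PROTEINAS", "B-UNCLEAR"],
            ["E-UNCLEAR", "M-UNCLEAR", "V-PROTEINAS", "B-UNCLEAR"],
            ["B-PROTEINAS", "B-PROTEINAS", "M-UNCLEAR", "O", "E-UNCLEAR"],
        ]
        for raw in raws:
            once = repair(raw, pharma_schema)
            assert repair(once, pharma_schema) == once
            assert is_well_formed(once, pharma_schema)

    def test_gold_sequences_are_well_formed(self, pharma_schema, small_corpus):
        for ts in small_corpus.sentences:
            assert is_well_formed(ts.sequence.tags, pharma_schema)


class TestBioExport:
    def test_prefix_mapping(self, pharma_schema):
        tags = ["O", "B-UNCLEAR", "M-UNCLEAR", "E-UNCLEAR", "W-PROTEINAS",
                "V-NORMALIZABLES"]
        assert to_bio(tags, pharma_schema) == [
            "O", "B-UNCLEAR", "I-UNCLEAR", "I-UNCLEAR", "B-PROTEINAS",
            "B-NORMALIZABLES",
        ]


class TestConll:
    def test_worked_example_table_layout(self, pharma_schema, doc_950):
        table = to_conll(doc_950, pharma_schema)
        sentences = [s for s in table.split("\n\n") if s.strip()]
        rows = [line.split("\t") for line in sentences[-1].splitlines() if line]
        assert len(rows) == 10
        assert rows[3] == ["corticoides", "NORMALIZABLES", "980", "991",
                           "W-NORMALIZABLES"]
        assert rows[8] == ["prednisona", "NORMALIZABLES", "1011", "1021",
                           "W-NORMALIZABLES"]

    def test_round_trip_tokens_and_tags(self, pharma_schema, small_corpus):
        for doc in small_corpus.documents:
            table = to_conll(doc, pharma_schema)
            sentences = from_conll(table)
            flat_tokens = [t for toks, _ in sentences for t in toks]
            flat_tags = [tag for _, tags in sentences for tag in tags]
            again = to_conll(doc, pharma_schema)
            assert again == table  # deterministic
            # re-parse matches the original token/tag stream
            flat2 = [
                (t.text, t.start, t.end)
                for s in from_conll(table)
                for t in s[0]
            ]
            assert flat2 == [(t.text, t.start, t.end) for t in flat_tokens]
            assert all(tag in pharma_schema.tags for tag in flat_tags)

    def test_empty_document_empty_table(self, pharma_schema):
        from clintagger.standoff import AnnotatedDocument, Document

        doc = AnnotatedDocument(Document("d", ""), [])
        assert from_conll(to_conll(doc, pharma_schema)) == []

    def test_ragged_row_raises_with_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            from_conll("tok\tOthers\t0\t3\tO\nbad\trow\n")

    def test_non_integer_offset_raises(self):
        with pytest.raises(ValueError, match="line 1"):
            from_conll("tok\tOthers\tzero\t3\tO\n")
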