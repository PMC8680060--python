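import pytest

from clintagger import (
    PHARMA_TYPES,
    AnnotatedDocument,
    Document,
    EntityMention,
    SyntheticCorpusSpec,
    TagSchema,
    generate_corpus,
)

# The worked example sentence: token offsets are document-level, anchored
# at offset 950 within its clinical case.
SENTENCE_950 = (
    "instaurándose tratamiento con corticoides orales en forma de "
    "prednisona oral"
)
SENTENCE_950_OFFSET = 950

EXPECTED_TOKENS_950 = [
    ("instaurándose", 950, 963),
    ("tratamiento", 964, 975),
    ("con", 976, 979),
    ("corticoides", 980, 991),
    ("orales", 992, 998),
    ("en", 999, 1001),
    ("forma", 1002, 1007),
    ("de", 1008, 1010),
    ("prednisona", 1011, 1021),
    ("oral", 1022, 1026),
]

GOLD_TAGS_950 = [
    "O", "O", "O", "W-NORMALIZABLES", "O", "O", "O", "O",
    "W-NORMALIZABLES", "O",
]


@pytest.fixture(scope="session")
def pharma_schema() -> TagSchema:
    return TagSchema(PHARMA_TYPES)


@pytest.fixture(scope="session")
def doc_950() -> AnnotatedDocument:
    """A document embedding the worked-example sentence at offset 950,
    with its two drug mentions annotated."""
    text = " " * SENTENCE_950_OFFSET + SENTENCE_950
    mentions = [
        EntityMention(980, 991, "NORMALIZABLES", "corticoides", "T1"),
        EntityMention(1011, 1021, "NORMALIZABLES", "prednisona", "T2"),
    ]
    return AnnotatedDocument(Document("case-950", text), mentions)


@pytest.fixture(scope="session")
def nested_doc() -> AnnotatedDocument:
    """The canonical nested pattern: a single-token mention inside a
    three-token one ("calcio" inside "calcio iónico corregido")."""
    text = "calcio iónico corregido"
    return AnnotatedDocument(
        Document("nested", text),
        [
            EntityMention(0, 23, "NORMALIZABLES", text, "T1"),
            EntityMention(0, 6, "NORMALIZABLES", "calcio", "T2"),
        ],
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic synthetic corpus exercising nesting,
    abbreviations and misspellings."""
    spec = SyntheticCorpusSpec(
        n_docs=6,
        sentences_per_doc=(3, 5),
        mention_rate=1.2,
        nesting_rate=0.3,
        misspelling_rate=0.2,
        abbreviation_rate=0.2,
        seed=42,
    )
    return generate_corpus(spec)
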