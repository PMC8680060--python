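"""Deterministic sentence splitting, offset-preserving tokenization, and
embedding-corpus text normalization.

Tokenization in clinical text is a known error source (hyphenated gene and
protein names such as ``S-100`` split differently across tools), so this
module uses an explicit rule set rather than delegating to a statistical
library: whitespace separation, punctuation isolation, configurable hyphen
splitting, decimal-number protection, and a protected-abbreviation list for
the sentence splitter.  All offsets are document-level unicode code points.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "SentenceSpan",
    "Token",
    "split_sentences",
    "tokenize",
    "tokenize_document",
    "normalize_corpus_text",
    "load_stopwords",
    "suffix_pos_tag",
    "DEFAULT_PROTECTED_ABBREVIATIONS",
]

#: Sentence-terminal periods are not split after these (lowercased, no dot).
DEFAULT_PROTECTED_ABBREVIATIONS = frozenset(
    {
        "dr", "dra", "sr", "sra", "srta", "prof", "etc", "vs", "fig", "figs",
        "no", "núm", "pág", "cap", "vol", "ej", "approx", "aprox", "mr", "mrs",
        "ms", "st", "e.g", "i.e",
    }
)

_TERMINALS = ".!?"


@dataclass(frozen=True)
class SentenceSpan:
    """Half-open character span of one sentence within a document."""

    start: int
    end: int


@dataclass(frozen=True)
class Token:
    """A token with document-level offsets and an optional coarse POS tag."""

    text: str
    start: int
    end: int
    pos_tag: Optional[str] = None


def _word_before(text: str, idx: int) -> str:
    """The maximal run of word characters (and internal dots) ending at idx."""
    j = idx
    while j > 0 and (text[j - 1].isalnum() or text[j - 1] == "."):
        j -= 1
    return text[j:idx]


def split_sentences(
    text: str,
    protected_abbreviations: frozenset[str] = DEFAULT_PROTECTED_ABBREVIATIONS,
) -> list[SentenceSpan]:
    """Split ``text`` into sentence spans.

    A sentence boundary is a terminal character (``. ! ?``) followed by
    whitespace and an uppercase letter, digit, or opening quote/bracket —
    unless the terminal is a decimal point between digits or follows a
    protected abbreviation.  Spans are trimmed to non-whitespace and cover
    every non-whitespace character exactly once.
    """
    spans: list[SentenceSpan] = []
    n = len(text)
    start = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch in _TERMINALS:
            # decimal point: 3.5
            if (
                ch == "."
                and 0 < i < n - 1
                and text[i - 1].isdigit()
                and text[i + 1].isdigit()
            ):
                i += 1
                continue
            if ch == "." and _word_before(text, i).lower().rstrip(".") in protected_abbreviations:
                i += 1
                continue
            # absorb runs of terminals ("?!", "...")
            j = i + 1
            while j < n and text[j] in _TERMINALS:
                j += 1
            k = j
            while k < n and text[k].isspace():
                k += 1
            if k == n or (k > j and (text[k].isupper() or text[k].isdigit() or text[k] in "\"'([¿¡")):
                spans.append(SentenceSpan(start, j))
                start = k
                i = k
                continue
            i = j
            continue
        i += 1
    if start < n and text[start:].strip():
        spans.append(SentenceSpan(start, n))
    # trim whitespace at span edges
    trimmed = []
    for s in spans:
        a, b = s.start, s.end
        while a < b and text[a].isspace():
            a += 1
        while b > a and text[b - 1].isspace():
            b -= 1
        if a < b:
            trimmed.append(SentenceSpan(a, b))
    return trimmed


def _is_word_char(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def tokenize(
    text: str,
    sentence: Optional[SentenceSpan] = None,
    split_hyphens: bool = True,
    pos_tagger=None,
) -> list[Token]:
    """Tokenize one sentence span of ``text`` into offset-bearing tokens.

    Runs of word characters form tokens; every punctuation character is
    isolated as its own token, except that a period between digits stays
    inside a number token and, with ``split_hyphens=False``, a hyphen
    between word characters stays inside its word.
    """
    if sentence is None:
        sentence = SentenceSpan(0, len(text))
    tokens: list[Token] = []
    i = sentence.start
    end = sentence.end
    while i < end:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if _is_word_char(ch):
            j = i + 1
            while j < end:
                c = text[j]
                if _is_word_char(c):
                    j += 1
                elif (
                    c == "."
                    and j + 1 < end
                    and text[j - 1].isdigit()
                    and text[j + 1].isdigit()
                ):
                    j += 2
                elif (
                    c == "-"
                    and not split_hyphens
                    and j + 1 < end
                    and _is_word_char(text[j + 1])
                ):
                    j += 2
                else:
                    break
            tokens.append(Token(text[i:j], i, j))
        else:
            tokens.append(Token(ch, i, i + 1))
            j = i + 1
        i = j
    if pos_tagger is not None:
        tokens = [
            Token(t.text, t.start, t.end, pos_tagger(t.text)) for t in tokens
        ]
    return tokens


def tokenize_document(
    text: str,
    split_hyphens: bool = True,
    pos_tagger=None,
    protected_abbreviations: frozenset[str] = DEFAULT_PROTECTED_ABBREVIATIONS,
) -> list[list[Token]]:
    """Sentence-split then tokenize; returns one token list per sentence."""
    return [
        tokenize(text, span, split_hyphens=split_hyphens, pos_tagger=pos_tagger)
        for span in split_sentences(text, protected_abbreviations)
    ]


def normalize_corpus_text(text: str, stopwords: Iterable[str] = ()) -> str:
    """Normalize raw corpus text for embedding training.

    Applies, in order: lowercasing, punctuation removal, whitespace
    collapsing, and stopword removal.  Idempotent.
    """
    stop = {s.lower() for s in stopwords}
    lowered = text.lower()
    cleaned = "".join(
        ch if (ch.isalnum() or ch.isspace()) else " " for ch in lowered
    )
    words = [w for w in cleaned.split() if w not in stop]
    return " ".join(words)


def load_stopwords(source: str | Path) -> frozenset[str]:
    """Load a one-term-per-line stopword list.

    ``source`` is either a language code with a packaged list (``"es"`` or
    ``"en"``) or a path to a UTF-8 text file.
    """
    if source in ("es", "en"):
        data = (
            resources.files("clintagger.data")
            .joinpath(f"stopwords_{source}.txt")
            .read_text(encoding="utf-8")
        )
    else:
        data = Path(source).read_text(encoding="utf-8")
    return frozenset(
        line.strip().lower() for line in data.splitlines() if line.strip()
    )


# Closed-class Spanish function words for the placeholder tagger.
_FUNCTION_WORDS = {
    "el": "DET", "la": "DET", "los": "DET", "las": "DET", "un": "DET",
    "una": "DET", "unos": "DET", "unas": "DET", "de": "ADP", "del": "ADP",
    "en": "ADP", "con": "ADP", "por": "ADP", "para": "ADP", "a": "ADP",
    "al": "ADP", "sin": "ADP", "sobre": "ADP", "tras": "ADP",
    "y": "CONJ", "o": "CONJ", "e": "CONJ", "u": "CONJ", "que": "CONJ",
    "se": "PRON", "su": "DET", "sus": "DET", "no": "ADV",
}

_SUFFIX_RULES: Sequence[tuple[str, str]] = (
    ("mente", "ADV"),
    ("ción", "NOUN"), ("sión", "NOUN"), ("ciones", "NOUN"), ("siones", "NOUN"),
    ("dad", "NOUN"), ("dades", "NOUN"), ("miento", "NOUN"), ("mientos", "NOUN"),
    ("ando", "VERB"), ("iendo", "VERB"), ("ándose", "VERB"), ("éndose", "VERB"),
    ("aba", "VERB"), ("aron", "VERB"), ("ieron", "VERB"),
    ("oso", "ADJ"), ("osa", "ADJ"), ("ivo", "ADJ"), ("iva", "ADJ"),
    ("ales", "ADJ"), ("ico", "ADJ"), ("ica", "ADJ"),
)


def suffix_pos_tag(token: str) -> str:
    """Naive suffix-based coarse POS tagger (testing placeholder only).

    Exists so sense-embedding ``token|POS`` lookup can be exercised without
    an external tagger; it is not a linguistic claim.
    """
    low = token.lower()
    if low in _FUNCTION_WORDS:
        return _FUNCTION_WORDS[low]
    if not any(c.isalpha() for c in token):
        return "NUM" if any(c.isdigit() for c in token) else "PUNCT"
    for suffix, tag in _SUFFIX_RULES:
        if low.endswith(suffix):
            return tag
    return "NOUN"
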