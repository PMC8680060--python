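"""BRAT standoff annotation I/O.

A corpus is a directory of paired ``<id>.txt`` / ``<id>.ann`` UTF-8 files.
Each entity line of an ``.ann`` file has the form::

    T1\tNORMALIZABLES 980 991\tcorticoides

Offsets are 0-based, end-exclusive, counted in unicode code points.
Normalization links are carried by N-lines (``N1\tReference T1 373757009``)
or, equivalently on input, by annotator-note comment lines
(``#1\tAnnotatorNotes T1\t373757009``).  Relation (R), event (E) and
attribute (A/M) lines are outside the scope of this toolkit and are skipped
with a logged notice.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "EntityMention",
    "AnnotatedDocument",
    "BratParseError",
    "parse_brat",
    "write_brat",
    "read_corpus_dir",
    "write_corpus_dir",
    "validate_corpus",
    "CorpusReport",
]


class BratParseError(ValueError):
    """Raised for malformed or inconsistent standoff lines."""

    def __init__(self, message: str, line: Optional[str] = None):
        self.line = line
        if line is not None:
            message = f"{message} [line: {line!r}]"
        super().__init__(message)


@dataclass(frozen=True)
class Document:
    """A raw text document with a corpus-unique identifier."""

    doc_id: str
    text: str


@dataclass(frozen=True, order=True)
class EntityMention:
    """A typed, contiguous character span, optionally linked to a concept.

    ``start``/``end`` are document-level code-point offsets, end-exclusive;
    ``surface`` must equal ``text[start:end]`` of the owning document.
    """

    start: int
    end: int
    entity_type: str
    surface: str
    mention_id: str = ""
    concept_id: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def contains(self, other: "EntityMention") -> bool:
        """Strict containment: ``other`` nested inside ``self``."""
        return (
            self.start <= other.start
            and other.end <= self.end
            and self.span != other.span
        )

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class AnnotatedDocument:
    """A document together with its (possibly nested) entity mentions."""

    document: Document
    mentions: list[EntityMention] = field(default_factory=list)

    @property
    def doc_id(self) -> str:
        return self.document.doc_id

    @property
    def text(self) -> str:
        return self.document.text

    def sorted_mentions(self) -> list[EntityMention]:
        return sorted(self.mentions, key=lambda m: (m.start, m.end, m.mention_id))


_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+(?: \d+)*(?:;\d+ \d+)*) ?(\d+)?\t?(.*)$")


def _parse_t_line(line: str, text: str) -> EntityMention:
    fields = line.split("\t")
    if len(fields) < 2:
        raise BratParseError("T-line must have at least two tab-separated fields", line)
    mention_id = fields[0]
    header = fields[1]
    stated_surface = fields[2] if len(fields) > 2 else None
    if ";" in header:
        raise BratParseError("unsupported fragment span (discontinuous mention)", line)
    parts = header.split()
    if len(parts) != 3:
        raise BratParseError("T-line header must be '<TYPE> <start> <end>'", line)
    entity_type, start_s, end_s = parts
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise BratParseError("non-integer offsets", line) from exc
    if not (0 <= start < end <= len(text)):
        raise BratParseError(
            f"offsets ({start}, {end}) out of range for text of length {len(text)}",
            line,
        )
    surface = text[start:end]
    if stated_surface is not None and stated_surface != "" and stated_surface != surface:
        raise BratParseError(
            f"surface mismatch: annotation says {stated_surface!r}, "
            f"text slice is {surface!r}",
            line,
        )
    return EntityMention(
        start=start,
        end=end,
        entity_type=entity_type,
        surface=surface,
        mention_id=mention_id,
    )


def _parse_norm_line(line: str) -> Optional[tuple[str, str]]:
    """Extract (target T-id, concept_id) from an N-line or #-note line."""
    fields = line.split("\t")
    if len(fields) < 2:
        return None
    tokens = fields[1].split()
    target = next((t for t in tokens if re.fullmatch(r"T\d+", t)), None)
    if target is None:
        return None
    if line.startswith("N"):
        # 'Reference T1 SNOMED:373757009' or 'Reference T1 373757009'
        concept = tokens[-1] if tokens[-1] != target else None
        if concept is None and len(fields) > 2:
            concept = fields[2].strip() or None
    else:
        # '#1\tAnnotatorNotes T1\t373757009'
        concept = fields[2].strip() if len(fields) > 2 else None
    if not concept:
        return None
    return target, concept


def parse_brat(text: str, ann_lines: Iterable[str], doc_id: str = "doc") -> AnnotatedDocument:
    """Parse standoff lines against ``text`` into an :class:`AnnotatedDocument`.

    T-lines become mentions (surface re-extracted from the text and checked
    against the stated surface); N-lines and #-notes attach concept IDs;
    other line kinds are skipped with a logged notice.
    """
    mentions: dict[str, EntityMention] = {}
    norm: dict[str, str] = {}
    for raw in ann_lines:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        kind = line[0]
        if kind == "T":
            mention = _parse_t_line(line, text)
            if mention.mention_id in mentions:
                raise BratParseError(
                    f"duplicate mention id {mention.mention_id}", line
                )
            mentions[mention.mention_id] = mention
        elif kind in "N#":
            link = _parse_norm_line(line)
            if link is not None:
                norm[link[0]] = link[1]
        else:
            logger.info("skipping non-entity annotation line kind %r: %s", kind, line)
    out = []
    for mid, mention in mentions.items():
        if mid in norm:
            mention = replace(mention, concept_id=norm[mid])
        out.append(mention)
    out.sort(key=lambda m: (m.start, m.end, m.mention_id))
    return AnnotatedDocument(Document(doc_id=doc_id, text=text), out)


def write_brat(doc: AnnotatedDocument) -> list[str]:
    """Serialize mentions to standoff lines (inverse of :func:`parse_brat`).

    Mentions are emitted in ascending (start, end) order; T-ids are
    renumbered sequentially and one N-line is written per concept link.
    """
    lines: list[str] = []
    norm_lines: list[str] = []
    for i, m in enumerate(doc.sorted_mentions(), start=1):
        if doc.text[m.start:m.end] != m.surface:
            raise ValueError(
                f"mention {m.mention_id or i} surface {m.surface!r} does not match "
                f"text slice {doc.text[m.start:m.end]!r}"
            )
        lines.append(f"T{i}\t{m.entity_type} {m.start} {m.end}\t{m.surface}")
        if m.concept_id is not None:
            norm_lines.append(f"N{len(norm_lines) + 1}\tReference T{i} {m.concept_id}")
    return lines + norm_lines


def read_corpus_dir(path: str | Path) -> list[AnnotatedDocument]:
    """Read a directory of paired ``.txt``/``.ann`` files, sorted by doc id."""
    path = Path(path)
    docs = []
    for txt in sorted(path.glob("*.txt")):
        ann = txt.with_suffix(".ann")
        text = txt.read_text(encoding="utf-8")
        ann_lines = ann.read_text(encoding="utf-8").splitlines() if ann.exists() else []
        docs.append(parse_brat(text, ann_lines, doc_id=txt.stem))
    return docs


def write_corpus_dir(docs: Sequence[AnnotatedDocument], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (path / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        (path / f"{doc.doc_id}.ann").write_text(
            "".join(line + "\n" for line in write_brat(doc)), encoding="utf-8"
        )


@dataclass
class DocReport:
    doc_id: str
    n_mentions: int
    nested_pairs: int
    overlap_pairs: int
    violations: list[str]


@dataclass
class CorpusReport:
    docs: list[DocReport]

    @property
    def violations(self) -> list[str]:
        return [v for d in self.docs for v in d.violations]

    @property
    def n_mentions(self) -> int:
        return sum(d.n_mentions for d in self.docs)

    @property
    def nested_pairs(self) -> int:
        return sum(d.nested_pairs for d in self.docs)

    @property
    def overlap_pairs(self) -> int:
        return sum(d.overlap_pairs for d in self.docs)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_corpus(docs: Iterable[AnnotatedDocument]) -> CorpusReport:
    """Check invariants and count nested / (non-nested) overlapping pairs.

    A pair is *nested* when one span strictly contains the other; pairs with
    identical spans or a partial crossing count as *overlap* pairs.
    """
    reports = []
    seen_doc_ids: set[str] = set()
    for doc in docs:
        violations: list[str] = []
        if doc.doc_id in seen_doc_ids:
            violations.append(f"duplicate doc_id {doc.doc_id!r}")
        seen_doc_ids.add(doc.doc_id)
        if doc.mentions and not doc.text:
            violations.append(f"{doc.doc_id}: annotated document with empty text")
        ids = [m.mention_id for m in doc.mentions if m.mention_id]
        if len(ids) != len(set(ids)):
            violations.append(f"{doc.doc_id}: duplicate mention ids")
        for m in doc.mentions:
            label = m.mention_id or f"({m.start},{m.end})"
            if not (0 <= m.start < m.end <= len(doc.text)):
                violations.append(
                    f"{doc.doc_id}/{label}: offsets ({m.start},{m.end}) out of "
                    f"range for text length {len(doc.text)}"
                )
                continue
            if doc.text[m.start:m.end] != m.surface:
                violations.append(
                    f"{doc.doc_id}/{label}: surface {m.surface!r} != text slice "
                    f"{doc.text[m.start:m.end]!r}"
                )
        nested = overlap = 0
        ms = doc.mentions
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                a, b = ms[i], ms[j]
                if a.contains(b) or b.contains(a):
                    nested += 1
                elif a.overlaps(b):
                    overlap += 1
        reports.append(
            DocReport(doc.doc_id, len(doc.mentions), nested, overlap, violations)
        )
    return CorpusReport(reports)
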