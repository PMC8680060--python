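"""The BMEWO-V tag scheme for (possibly nested) entity mentions.

BMEWO-V extends the BIOES/BMEWO prefix family with a V tag for tokens
covered by more than one mention, which lets a flat per-token tagging
represent the nesting pattern common in clinical text (a single-token
mention inside a longer one, e.g. "calcio" inside "calcio iónico
corregido").

Conventions implemented here:

* ``encode`` — a token covered by exactly one mention receives W (the
  mention is that single token) or B/M/E by position; a token covered by
  two or more mentions receives ``V-<type>`` where ``<type>`` is the
  *innermost* (shortest) covering mention's type; all other tokens are O.
* ``decode`` — each maximal B…E run (V tokens may stand anywhere in the
  run, including in place of B or E) yields the enclosing mention, plus one
  single-token mention per V token, typed by the V tag.  A V token adjacent
  to no continuing run is a standalone single-token mention.

Consequence (documented limitation): only nestings whose inner mention is a
single token round-trip exactly; multi-token inner mentions collapse to
their per-token readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .preprocess import Token
from .standoff import AnnotatedDocument, Document, EntityMention

__all__ = [
    "PREFIXES",
    "OUTSIDE",
    "TagSchema",
    "TagSequence",
    "build_tagset",
    "encode",
    "decode",
    "repair",
    "is_well_formed",
    "to_bio",
    "to_conll",
    "from_conll",
    "MisalignedMentionError",
]

PREFIXES = ("B", "M", "E", "W", "V")
OUTSIDE = "O"


class MisalignedMentionError(ValueError):
    """A mention boundary falls inside a token."""


@dataclass(frozen=True)
class TagSchema:
    """Tag inventory for a fixed, ordered set of entity types."""

    entity_types: tuple[str, ...]

    def __post_init__(self):
        if not self.entity_types:
            raise ValueError("entity_types must be non-empty")
        if len(set(self.entity_types)) != len(self.entity_types):
            raise ValueError(f"duplicate entity type in {self.entity_types}")
        object.__setattr__(self, "entity_types", tuple(self.entity_types))

    @property
    def tags(self) -> tuple[str, ...]:
        """Inventory in deterministic order: type-major, prefix order
        B, M, E, W, V, with O last.  Size = 5·T + 1."""
        return tuple(
            f"{p}-{t}" for t in self.entity_types for p in PREFIXES
        ) + (OUTSIDE,)

    @property
    def tag_to_index(self) -> dict[str, int]:
        return {tag: i for i, tag in enumerate(self.tags)}

    def __len__(self) -> int:
        return 5 * len(self.entity_types) + 1

    def split(self, tag: str) -> tuple[str, Optional[str]]:
        """Return (prefix, type); O maps to ("O", None)."""
        if tag == OUTSIDE:
            return OUTSIDE, None
        prefix, _, etype = tag.partition("-")
        if prefix not in PREFIXES or etype not in self.entity_types:
            raise ValueError(f"tag {tag!r} not in schema inventory")
        return prefix, etype


def build_tagset(entity_types: Sequence[str]) -> tuple[str, ...]:
    """Ordered BMEWO-V inventory for ``entity_types`` (5·T + 1 tags)."""
    return TagSchema(tuple(entity_types)).tags


@dataclass
class TagSequence:
    """Per-token tags aligned with a token sequence."""

    tokens: list[Token]
    tags: list[str]
    raw: bool = False  # True for unrepaired model output

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValueError(
                f"{len(self.tags)} tags for {len(self.tokens)} tokens"
            )


def encode(
    tokens: Sequence[Token],
    mentions: Iterable[EntityMention],
    schema: TagSchema,
    misalignment: Literal["error", "snap-and-warn"] = "error",
) -> TagSequence:
    """Encode mention spans over ``tokens`` as BMEWO-V tags."""
    tokens = list(tokens)
    if not tokens:
        return TagSequence([], [])
    sent_start, sent_end = tokens[0].start, tokens[-1].end
    mentions = [
        m for m in mentions if m.start < sent_end and sent_start < m.end
    ]
    boundaries_start = {t.start for t in tokens}
    boundaries_end = {t.end for t in tokens}
    aligned: list[EntityMention] = []
    for m in mentions:
        if m.start in boundaries_start and m.end in boundaries_end:
            aligned.append(m)
        elif misalignment == "snap-and-warn":
            snapped_start = max(
                (s for s in boundaries_start if s <= m.start), default=sent_start
            )
            snapped_end = min(
                (e for e in boundaries_end if e >= m.end), default=sent_end
            )
            import logging

            logging.getLogger(__name__).warning(
                "snapping misaligned mention %s (%d,%d) -> (%d,%d)",
                m.mention_id, m.start, m.end, snapped_start, snapped_end,
            )
            aligned.append(
                EntityMention(
                    snapped_start, snapped_end, m.entity_type,
                    surface=m.surface, mention_id=m.mention_id,
                    concept_id=m.concept_id,
                )
            )
        else:
            raise MisalignedMentionError(
                f"mention {m.mention_id or m.surface!r} ({m.start},{m.end}) "
                "does not align with token boundaries"
            )

    # token index span of each mention
    span_of: dict[int, tuple[int, int]] = {}
    for k, m in enumerate(aligned):
        idxs = [
            i for i, t in enumerate(tokens) if m.start <= t.start and t.end <= m.end
        ]
        if idxs:
            span_of[k] = (idxs[0], idxs[-1])

    tags = [OUTSIDE] * len(tokens)
    for i, tok in enumerate(tokens):
        covering = [
            (aligned[k], span_of[k]) for k in span_of
            if span_of[k][0] <= i <= span_of[k][1]
        ]
        if not covering:
            continue
        if len(covering) >= 2:
            inner = min(
                covering,
                key=lambda pair: (
                    pair[0].end - pair[0].start, pair[0].start, pair[0].entity_type
                ),
            )[0]
            tags[i] = f"V-{inner.entity_type}"
        else:
            m, (first, last) = covering[0]
            if first == last:
                prefix = "W"
            elif i == first:
                prefix = "B"
            elif i == last:
                prefix = "E"
            else:
                prefix = "M"
            tags[i] = f"{prefix}-{m.entity_type}"
    seq = TagSequence(tokens, tags)
    for tag in seq.tags:
        schema.split(tag)  # raises on out-of-inventory types
    return seq


def decode(seq: TagSequence, schema: TagSchema, text: Optional[str] = None) -> list[EntityMention]:
    """Decode a well-formed BMEWO-V sequence back into mentions.

    ``text``, when given, supplies mention surfaces (otherwise surfaces are
    reconstructed by joining token texts with single spaces).
    """
    tokens, tags = seq.tokens, seq.tags
    mentions: list[EntityMention] = []

    def surface(first: int, last: int) -> str:
        if text is not None:
            return text[tokens[first].start:tokens[last].end]
        return " ".join(t.text for t in tokens[first:last + 1])

    def emit(first: int, last: int, etype: str) -> None:
        mentions.append(
            EntityMention(
                tokens[first].start, tokens[last].end, etype,
                surface=surface(first, last),
            )
        )

    n = len(tags)
    i = 0
    while i < n:
        prefix, etype = schema.split(tags[i])
        if prefix == OUTSIDE:
            i += 1
        elif prefix == "W":
            emit(i, i, etype)
            i += 1
        elif prefix in ("B", "V"):
            run_start = i
            outer_type = etype if prefix == "B" else None
            v_positions: list[tuple[int, str]] = (
                [(i, etype)] if prefix == "V" else []
            )
            j = i + 1
            end_index = None
            while j < n:
                p, t = schema.split(tags[j])
                if p == "M":
                    outer_type = outer_type or t
                    j += 1
                elif p == "V":
                    v_positions.append((j, t))
                    j += 1
                elif p == "E":
                    outer_type = outer_type or t
                    end_index = j
                    j += 1
                    break
                else:
                    break
            run_end = end_index if end_index is not None else j - 1
            if outer_type is not None and run_end > run_start:
                emit(run_start, run_end, outer_type)
            elif outer_type is not None and not v_positions:
                emit(run_start, run_end, outer_type)  # degenerate one-token run
            for pos, vtype in v_positions:
                emit(pos, pos, vtype)
            i = j
        else:
            raise ValueError(
                f"cannot decode raw tag {tags[i]!r} at position {i}; "
                "repair the sequence first"
            )
    for m in mentions:
        assert m.start < m.end
    mentions.sort(key=lambda m: (m.start, m.end, m.entity_type))
    return [
        EntityMention(m.start, m.end, m.entity_type, m.surface, f"T{k + 1}")
        for k, m in enumerate(mentions)
    ]


def is_well_formed(tags: Sequence[str], schema: TagSchema) -> bool:
    """Check B…E pairing: M/E only continue a same-type run opened by B
    (or by V); V is permitted anywhere, including closing a run (the
    pattern produced by an outer mention whose nested token is last)."""
    open_type: Optional[str] = None  # None = closed, "?" = opened by V
    last_was_v = False
    for tag in tags:
        prefix, etype = schema.split(tag)
        if prefix in (OUTSIDE, "W", "B"):
            if open_type not in (None, "?") and not last_was_v:
                return False
            open_type = etype if prefix == "B" else None
            last_was_v = False
        elif prefix == "V":
            if open_type is None:
                open_type = "?"
            last_was_v = True
        elif prefix == "M":
            if open_type not in ("?", etype):
                return False
            open_type = etype
            last_was_v = False
        elif prefix == "E":
            if open_type not in ("?", etype):
                return False
            open_type = None
            last_was_v = False
    return open_type in (None, "?") or last_was_v


def repair(raw_tags: Sequence[str], schema: TagSchema) -> list[str]:
    """Deterministically repair a raw model-output tag sequence.

    Orphan M/E become B-runs or W; a type change mid-run closes the
    previous run (its last tag becomes E, or W for one-token runs).
    Idempotent; output passes :func:`is_well_formed`.
    """
    out: list[str] = []
    open_type: Optional[str] = None
    run_positions: list[int] = []  # indices in out of non-V run members

    def close_run() -> None:
        nonlocal open_type, run_positions
        if open_type is None or not run_positions:
            open_type = None
            run_positions = []
            return
        if out and schema.split(out[-1])[0] == "V":
            # a run ending in V is already validly closed
            open_type = None
            run_positions = []
            return
        last = run_positions[-1]
        p, t = schema.split(out[last])
        if len(run_positions) == 1:
            if p in ("B", "M"):
                out[last] = f"W-{t}"
        elif p in ("B", "M"):
            out[last] = f"E-{t}"
        open_type = None
        run_positions = []

    for tag in raw_tags:
        prefix, etype = schema.split(tag)
        if prefix == OUTSIDE:
            close_run()
            out.append(OUTSIDE)
        elif prefix == "W":
            close_run()
            out.append(tag)
        elif prefix == "B":
            close_run()
            out.append(tag)
            open_type = etype
            run_positions = [len(out) - 1]
        elif prefix == "M":
            if open_type == etype or open_type == "?":
                out.append(tag)
                open_type = etype
                run_positions.append(len(out) - 1)
            else:
                close_run()
                out.append(f"B-{etype}")
                open_type = etype
                run_positions = [len(out) - 1]
        elif prefix == "E":
            if open_type == etype or open_type == "?":
                out.append(tag)
                run_positions.append(len(out) - 1)
                open_type = None
                run_positions = []
            else:
                close_run()
                out.append(f"W-{etype}")
        elif prefix == "V":
            out.append(tag)
            if open_type is None:
                open_type = "?"
                run_positions = []
    # close a dangling B/M run at sequence end
    if open_type not in (None, "?"):
        close_run()
    return out


def to_bio(tags: Sequence[str], schema: TagSchema) -> list[str]:
    """BIO export shim: B→B, M/E→I, W→B, V→B of the V tag's type."""
    out = []
    for tag in tags:
        prefix, etype = schema.split(tag)
        if prefix == OUTSIDE:
            out.append(OUTSIDE)
        elif prefix in ("B", "W", "V"):
            out.append(f"B-{etype}")
        else:  # M, E
            out.append(f"I-{etype}")
    return out


# ---------------------------------------------------------------------------
# CoNLL-2003-style interchange: token \t entity \t start \t end \t tag,
# blank line between sentences.

_OTHERS = "Others"


def to_conll(
    doc: AnnotatedDocument,
    schema: TagSchema,
    split_hyphens: bool = True,
    bio_column: bool = False,
    misalignment: Literal["error", "snap-and-warn"] = "error",
) -> str:
    """Render a document as a CoNLL-2003-style TSV table."""
    from .preprocess import tokenize_document

    lines: list[str] = []
    for tokens in tokenize_document(doc.text, split_hyphens=split_hyphens):
        seq = encode(tokens, doc.mentions, schema, misalignment=misalignment)
        bio = to_bio(seq.tags, schema) if bio_column else None
        for k, (tok, tag) in enumerate(zip(seq.tokens, seq.tags)):
            _, etype = schema.split(tag)
            row = [tok.text, etype or _OTHERS, str(tok.start), str(tok.end), tag]
            if bio is not None:
                row.append(bio[k])
            lines.append("\t".join(row))
        lines.append("")
    return "\n".join(lines)


def from_conll(text: str) -> list[tuple[list[Token], list[str]]]:
    """Parse CoNLL rows back into per-sentence (tokens, tags) pairs."""
    sentences: list[tuple[list[Token], list[str]]] = []
    tokens: list[Token] = []
    tags: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            if tokens:
                sentences.append((tokens, tags))
                tokens, tags = [], []
            continue
        if line.startswith("-DOCSTART-"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"line {lineno}: expected >= 5 columns, got {len(fields)}")
        word, _etype, start_s, end_s, tag = fields[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer offsets") from exc
        tokens.append(Token(word, start, end))
        tags.append(tag)
    if tokens:
        sentences.append((tokens, tags))
    return sentences
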