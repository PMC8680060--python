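"""Two-stage dictionary concept normalization.

A recognized mention is mapped to a terminology identifier by the pipeline

    lowercase → abbreviation expansion → exact term match
    → bounded-Levenshtein match (distance ≤ max_edit_distance)
    → thresholded fuzzy match (similarity 1 − d/max(|a|,|b|) ≥ threshold)
    → unmatched

mirroring the full-text-search-then-fuzzy-search strategy used with large
clinical terminologies (SNOMED-CT and the AbreMES-DB / SEDOM abbreviation
resources, which are licensed and therefore not shipped; any TSV dictionary
of the same shape works).  ``conceptize_text`` applies the same dictionary
to running text, replacing terms with their concept identifiers — the
transform used to build concept-level embedding corpora.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

from .standoff import AnnotatedDocument

logger = logging.getLogger(__name__)

__all__ = [
    "levenshtein",
    "similarity",
    "ConceptDictionary",
    "AbbreviationDictionary",
    "NormalizerConfig",
    "NormalizationResult",
    "expand_abbreviations",
    "normalize_mention",
    "normalize_corpus",
    "conceptize_text",
]


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character insertions, deletions and
    substitutions transforming ``a`` into ``b`` (two-row dynamic program)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,          # deletion
                cur[j - 1] + 1,       # insertion
                prev[j - 1] + (ca != cb),  # substitution
            )
        prev = cur
    return prev[-1]


def similarity(a: str, b: str) -> float:
    """Normalized similarity 1 − d/max(|a|,|b|) in [0, 1]."""
    if not a and not b:
        return 1.0
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


@dataclass
class ConceptDictionary:
    """concept_id → set of (case-normalized) terms, with an inverted index."""

    entries: dict[str, set[str]]
    term_index: dict[str, list[str]] = field(init=False)

    def __post_init__(self):
        cleaned: dict[str, set[str]] = {}
        index: dict[str, list[str]] = defaultdict(list)
        for cid, terms in self.entries.items():
            norm = {t.strip().lower() for t in terms}
            if any(not t for t in norm):
                raise ValueError(f"empty term for concept {cid}")
            cleaned[cid] = norm
            for t in norm:
                index[t].append(cid)
        self.entries = cleaned
        self.term_index = {t: sorted(ids) for t, ids in index.items()}

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_index)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConceptDictionary":
        """Read ``concept_id<TAB>term`` rows (one row per pair)."""
        entries: dict[str, set[str]] = defaultdict(set)
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            entries[parts[0]].add(parts[1])
        return cls(dict(entries))

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{cid}\t{term}"
            for cid in sorted(self.entries)
            for term in sorted(self.entries[cid])
        ]
        Path(path).write_text("".join(l + "\n" for l in lines), encoding="utf-8")


@dataclass
class AbbreviationDictionary:
    """abbreviation → full concept name (keys unique after lowercasing)."""

    entries: dict[str, str]

    def __post_init__(self):
        lowered: dict[str, str] = {}
        for k, v in self.entries.items():
            key = k.strip().lower()
            if key in lowered and lowered[key] != v.strip().lower():
                raise ValueError(f"conflicting expansions for abbreviation {key!r}")
            lowered[key] = v.strip().lower()
        self.entries = lowered
        self.max_key_tokens = max(
            (len(k.split()) for k in lowered), default=1
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbbreviationDictionary":
        entries = {}
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            entries[parts[0]] = parts[1]
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{k}\t{v}" for k, v in sorted(self.entries.items())]
        Path(path).write_text("".join(l + "\n" for l in lines), encoding="utf-8")


@dataclass
class NormalizerConfig:
    max_edit_distance: int = 1
    fuzzy_threshold: float = 0.80
    ambiguity_policy: Literal["first-by-id", "reject"] = "first-by-id"

    def __post_init__(self):
        if self.max_edit_distance < 0:
            raise ValueError("max_edit_distance must be >= 0")
        if not (0.0 < self.fuzzy_threshold <= 1.0):
            raise ValueError("fuzzy_threshold must be in (0, 1]")


@dataclass
class NormalizationResult:
    concept_id: Optional[str]
    stage: Literal["exact", "levenshtein", "fuzzy", "unmatched"]
    score: float  # edit distance for exact/levenshtein, similarity for fuzzy
    matched_term: Optional[str] = None
    ambiguous: bool = False

    def __post_init__(self):
        assert (self.stage == "unmatched") == (self.concept_id is None)


def expand_abbreviations(mention: str, abbrevs: AbbreviationDictionary) -> str:
    """Replace whole-token abbreviations with their full names.

    Greedy, left-to-right, longest key (in tokens) first; tokens not in the
    dictionary are left unchanged.  The mention should be lowercased first.
    """
    tokens = mention.split()
    out: list[str] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(abbrevs.max_key_tokens, len(tokens) - i), 0, -1):
            key = " ".join(tokens[i:i + n])
            if key in abbrevs.entries:
                out.append(abbrevs.entries[key])
                i += n
                matched = True
                break
        if not matched:
            out.append(tokens[i])
            i += 1
    return " ".join(out)


def _resolve(
    candidates: Sequence[str], policy: str
) -> tuple[Optional[str], bool]:
    """Pick a concept id among candidates; returns (id, ambiguous)."""
    ids = sorted(set(candidates))
    if len(ids) == 1:
        return ids[0], False
    if policy == "reject":
        return None, True
    return ids[0], True


def normalize_mention(
    mention: str,
    dictionary: ConceptDictionary,
    abbrevs: Optional[AbbreviationDictionary] = None,
    cfg: Optional[NormalizerConfig] = None,
) -> NormalizationResult:
    """Map one mention surface to a concept id via the two-stage search."""
    cfg = cfg or NormalizerConfig()
    query = mention.strip().lower()
    if abbrevs is not None:
        query = expand_abbreviations(query, abbrevs)

    # stage 0: exact term match
    if query in dictionary.term_index:
        cid, ambiguous = _resolve(dictionary.term_index[query], cfg.ambiguity_policy)
        if cid is not None:
            return NormalizationResult(cid, "exact", 0.0, query, ambiguous)
        return NormalizationResult(None, "unmatched", 0.0, query, True)

    # stage 1: bounded-distance full-text search
    if cfg.max_edit_distance > 0:
        best_d = cfg.max_edit_distance + 1
        best_terms: list[str] = []
        for term in dictionary.terms:
            if abs(len(term) - len(query)) > cfg.max_edit_distance:
                continue
            d = levenshtein(query, term)
            if d < best_d:
                best_d, best_terms = d, [term]
            elif d == best_d:
                best_terms.append(term)
        if best_d <= cfg.max_edit_distance:
            term = sorted(best_terms)[0]
            ids = [cid for t in best_terms for cid in dictionary.term_index[t]]
            cid, ambiguous = _resolve(ids, cfg.ambiguity_policy)
            if cid is not None:
                # report the term actually carrying the chosen id
                term = sorted(
                    t for t in best_terms if cid in dictionary.term_index[t]
                )[0]
                return NormalizationResult(cid, "levenshtein", float(best_d), term, ambiguous)
            return NormalizationResult(None, "unmatched", float(best_d), None, True)

    # stage 2: thresholded fuzzy search
    best_sim = -1.0
    best_terms = []
    for term in dictionary.terms:
        s = similarity(query, term)
        if s > best_sim + 1e-12:
            best_sim, best_terms = s, [term]
        elif abs(s - best_sim) <= 1e-12:
            best_terms.append(term)
    if best_sim >= cfg.fuzzy_threshold and best_terms:
        ids = [cid for t in best_terms for cid in dictionary.term_index[t]]
        cid, ambiguous = _resolve(ids, cfg.ambiguity_policy)
        if cid is not None:
            term = sorted(
                t for t in best_terms if cid in dictionary.term_index[t]
            )[0]
            return NormalizationResult(cid, "fuzzy", best_sim, term, ambiguous)
        return NormalizationResult(None, "unmatched", best_sim, None, True)

    return NormalizationResult(None, "unmatched", best_sim, None)


def normalize_corpus(
    docs: Iterable[AnnotatedDocument],
    dictionary: ConceptDictionary,
    abbrevs: Optional[AbbreviationDictionary] = None,
    cfg: Optional[NormalizerConfig] = None,
) -> tuple[list[AnnotatedDocument], Counter]:
    """Fill ``concept_id`` on every mention; returns (documents, stage counts)."""
    cfg = cfg or NormalizerConfig()
    out_docs: list[AnnotatedDocument] = []
    stages: Counter = Counter()
    for doc in docs:
        mentions = []
        for m in doc.mentions:
            result = normalize_mention(m.surface, dictionary, abbrevs, cfg)
            stages[result.stage] += 1
            mentions.append(replace(m, concept_id=result.concept_id))
        out_docs.append(AnnotatedDocument(doc.document, mentions))
    logger.info("normalization stages: %s", dict(stages))
    return out_docs, stages


def conceptize_text(text: str, dictionary: ConceptDictionary) -> str:
    """Replace dictionary terms in running text with their concept ids.

    Matching is on whitespace-token boundaries, non-overlapping,
    longest-match-first, left to right; ambiguous terms take the smallest
    concept id.  The input is expected to be case-normalized already.
    """
    by_token_count: dict[int, dict[str, str]] = defaultdict(dict)
    for term, ids in dictionary.term_index.items():
        by_token_count[len(term.split())][term] = ids[0]
    if not by_token_count:
        return text
    max_n = max(by_token_count)
    tokens = text.split()
    out: list[str] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            candidate = " ".join(tokens[i:i + n])
            if candidate in by_token_count.get(n, {}):
                out.append(by_token_count[n][candidate])
                i += n
                matched = True
                break
        if not matched:
            out.append(tokens[i])
            i += 1
    return " ".join(out)
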