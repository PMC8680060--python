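"""Seeded generator of toy Spanish-like clinical corpora with gold
annotations, exercising every pipeline stage without external downloads.

The generator emulates short clinical-case sentences carrying mentions of
four entity classes (the drug/chemical/protein inventory used by Spanish
clinical NER), with controlled rates of nested mentions (the recoverable
pattern: a single-token inner mention inside a multi-token one), mentions
rendered as abbreviations, and mention surfaces misspelled at an exact
target edit distance.  Every mention carries its gold concept id, gold
BMEWO-V tags are included per sentence, and an identical spec + seed always
reproduces the identical corpus.

What it does *not* emulate: real class frequencies, discourse structure,
real Spanish morphology, annotation noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .codec import TagSchema, TagSequence, encode
from .normalize import AbbreviationDictionary, ConceptDictionary, levenshtein
from .preprocess import tokenize_document
from .standoff import AnnotatedDocument, Document, EntityMention

__all__ = [
    "PHARMA_TYPES",
    "SyntheticCorpusSpec",
    "SyntheticCorpus",
    "make_dictionary",
    "perturb_term",
    "generate_corpus",
]

PHARMA_TYPES = ("NORMALIZABLES", "NO_NORMALIZABLES", "PROTEINAS", "UNCLEAR")

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

# Carrier templates by number of mention slots; every template starts with a
# capitalized word so the rule-based sentence splitter finds the boundaries.
_TEMPLATES_0 = (
    "El paciente permanece estable durante el ingreso.",
    "La evolución clínica resulta favorable.",
    "Se decide alta hospitalaria con control ambulatorio.",
)
_TEMPLATES_1 = (
    "Se pauta {} durante el ingreso.",
    "Se administra {} tras la intervención.",
    "El paciente recibe {} por vía oral.",
    "Se suspende {} por toxicidad.",
    "Los niveles de {} permanecen dentro de la normalidad.",
    "La analítica muestra {} elevada.",
    "No presenta alergia conocida a {}.",
)
_TEMPLATES_2 = (
    "Se inicia tratamiento con {} y {} durante la estancia.",
    "Recibe {} junto con {} en pauta descendente.",
    "El control analítico incluye {} y también {}.",
)


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Generator parameters; identical spec + seed → identical corpus."""

    n_docs: int = 10
    sentences_per_doc: tuple[int, int] = (5, 5)
    entity_types: tuple[str, ...] = PHARMA_TYPES
    mention_rate: float = 1.0
    nesting_rate: float = 0.0
    misspelling_rate: float = 0.0
    misspelling_distance: int = 1
    abbreviation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("mention_rate",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nesting_rate", "misspelling_rate", "abbreviation_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.misspelling_distance < 1:
            raise ValueError("misspelling_distance must be >= 1")


@dataclass
class TaggedSentence:
    doc_id: str
    sentence_index: int
    sequence: TagSequence


@dataclass
class SyntheticCorpus:
    documents: list[AnnotatedDocument]
    sentences: list[TaggedSentence]
    dictionary: ConceptDictionary
    abbreviations: AbbreviationDictionary
    concept_types: dict[str, str]
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2, sort_keys=True)


def _syllable(rng: np.random.Generator) -> str:
    return str(rng.choice(list(_CONSONANTS))) + str(rng.choice(list(_VOWELS)))


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


def make_dictionary(
    n_concepts: int,
    seed: int = 0,
    tokens_per_term: tuple[int, int] = (1, 3),
    min_pairwise_distance: int = 3,
    abbreviation_fraction: float = 0.3,
    max_term_length: int = 24,
) -> tuple[ConceptDictionary, AbbreviationDictionary, dict[str, str]]:
    """Generate pronounceable multi-token terms, one per concept.

    Terms are rejection-sampled so every pair is at Levenshtein distance
    ≥ ``min_pairwise_distance`` (with the default misspelling distance of 1
    this guarantees a unique nearest term for every perturbed surface).  A
    fraction of concepts receives an abbreviation (the initial letters of
    the term's tokens).  Returns (concepts, abbreviations, concept→type
    assignment placeholder filled by :func:`generate_corpus`).
    """
    if n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    rng = np.random.default_rng(seed)
    terms: list[str] = []
    attempts = 0
    while len(terms) < n_concepts:
        attempts += 1
        if attempts > 2000 * n_concepts:
            raise RuntimeError(
                "could not sample sufficiently separated terms; relax "
                "min_pairwise_distance or shorten the dictionary"
            )
        n_tok = int(rng.integers(tokens_per_term[0], tokens_per_term[1] + 1))
        term = " ".join(_word(rng, int(rng.integers(2, 5))) for _ in range(n_tok))
        if len(term) > max_term_length:
            continue
        if all(levenshtein(term, t) >= min_pairwise_distance for t in terms):
            terms.append(term)
    ids = [f"{100000 + 7 * k}" for k in range(n_concepts)]
    entries = {cid: {term} for cid, term in zip(ids, terms)}

    abbrevs: dict[str, str] = {}
    n_abbrev = int(round(abbreviation_fraction * n_concepts))
    order = rng.permutation(n_concepts)
    used: set[str] = set(terms)
    for k in order:
        if len(abbrevs) >= n_abbrev:
            break
        term = terms[k]
        toks = term.split()
        cand = "".join(t[0] for t in toks) if len(toks) > 1 else term[:2]
        if cand in used or cand in abbrevs or len(cand) < 2:
            cand = (cand + term.replace(" ", "")[len(cand):len(cand) + 1])
        if cand and cand not in used and cand not in abbrevs:
            abbrevs[cand] = term
            used.add(cand)
    return (
        ConceptDictionary(entries),
        AbbreviationDictionary(abbrevs),
        {cid: term for cid, term in zip(ids, terms)},
    )


def perturb_term(term: str, distance: int, seed: int = 0) -> str:
    """Misspell ``term`` at exactly the requested Levenshtein distance.

    Edits touch only letter positions (never the spaces of a multi-token
    term), so token boundaries survive.  The realized distance is verified
    by computation and the edit is re-drawn if the composition collapses.
    """
    if distance == 0:
        return term
    if distance >= len(term):
        raise ValueError(
            f"distance {distance} must be < term length {len(term)}"
        )
    rng = np.random.default_rng(seed)
    letters = "abcdefghijklmnopqrstuvwxyz"
    for _attempt in range(200):
        out = term
        for _ in range(distance):
            positions = [i for i, ch in enumerate(out) if ch != " "]
            op = rng.choice(["substitute", "insert", "delete"])
            if op == "delete" and len(out) <= 2:
                op = "substitute"
            if op == "substitute":
                i = int(rng.choice(positions))
                repl = str(rng.choice(list(letters.replace(out[i], ""))))
                out = out[:i] + repl + out[i + 1:]
            elif op == "insert":
                i = int(rng.choice(positions)) + 1
                out = out[:i] + str(rng.choice(list(letters))) + out[i:]
            else:
                i = int(rng.choice(positions))
                out = out[:i] + out[i + 1:]
        if out != term and levenshtein(term, out) == distance and " ".join(out.split()) == out:
            return out
    raise RuntimeError(f"could not realize distance {distance} for {term!r}")


def generate_corpus(
    spec: SyntheticCorpusSpec,
    dictionary: Optional[ConceptDictionary] = None,
    abbreviations: Optional[AbbreviationDictionary] = None,
    concept_terms: Optional[dict[str, str]] = None,
) -> SyntheticCorpus:
    """Generate an annotated corpus from carrier templates.

    When no dictionary is supplied one is generated from the spec seed
    (60 concepts, pairwise distance ≥ max(3, 2·misspelling_distance + 1) so
    perturbed surfaces keep a unique nearest term).
    """
    rng = np.random.default_rng(spec.seed)
    if dictionary is None:
        dictionary, abbreviations, concept_terms = make_dictionary(
            60,
            seed=spec.seed,
            min_pairwise_distance=max(3, 2 * spec.misspelling_distance + 1),
        )
    if concept_terms is None:
        concept_terms = {cid: sorted(ts)[0] for cid, ts in dictionary.entries.items()}
    if abbreviations is None:
        abbreviations = AbbreviationDictionary({})
    abbrev_of = {term: ab for ab, term in abbreviations.entries.items()}
    concept_ids = sorted(concept_terms)
    concept_type = {
        cid: spec.entity_types[int(rng.integers(len(spec.entity_types)))]
        for cid in concept_ids
    }
    # Nesting is a property of the concept, decided once per corpus, so the
    # same surface string is annotated consistently wherever it appears
    # (as in real annotation guidelines): a multi-token concept selected
    # here always carries an inner single-token mention of a fixed type.
    nested_inner_type: dict[str, str] = {}
    for cid in concept_ids:
        if " " in concept_terms[cid] and rng.random() < spec.nesting_rate:
            nested_inner_type[cid] = spec.entity_types[
                int(rng.integers(len(spec.entity_types)))
            ]
    schema = TagSchema(spec.entity_types)

    documents: list[AnnotatedDocument] = []
    tagged: list[TaggedSentence] = []
    counts = {
        "documents": 0, "sentences": 0, "mentions": 0, "nested": 0,
        "abbreviated": 0, "misspelled": 0,
    }

    for d in range(spec.n_docs):
        doc_id = f"synth-{spec.seed:04d}-{d:03d}"
        n_sent = int(
            rng.integers(spec.sentences_per_doc[0], spec.sentences_per_doc[1] + 1)
        )
        text_parts: list[str] = []
        mentions: list[EntityMention] = []
        offset = 0
        mention_counter = 0
        for s in range(n_sent):
            k = min(int(rng.poisson(spec.mention_rate)), 2)
            template = {
                0: _TEMPLATES_0, 1: _TEMPLATES_1, 2: _TEMPLATES_2,
            }[k][int(rng.integers(len({0: _TEMPLATES_0, 1: _TEMPLATES_1, 2: _TEMPLATES_2}[k])))]
            surfaces: list[tuple[str, str, Optional[str], bool, bool]] = []
            for _ in range(k):
                cid = concept_ids[int(rng.integers(len(concept_ids)))]
                term = concept_terms[cid]
                surface = term
                abbreviated = misspelled = False
                if term in abbrev_of and rng.random() < spec.abbreviation_rate:
                    surface = abbrev_of[term]
                    abbreviated = True
                elif rng.random() < spec.misspelling_rate:
                    surface = perturb_term(
                        term, spec.misspelling_distance,
                        seed=int(rng.integers(2 ** 31)),
                    )
                    misspelled = True
                surfaces.append(
                    (surface, concept_type[cid], cid, abbreviated, misspelled)
                )
            # realize the sentence and compute mention offsets
            pieces = template.split("{}")
            sent = pieces[0]
            sent_mentions: list[EntityMention] = []
            for piece_idx, (surface, etype, cid, abbreviated, misspelled) in enumerate(surfaces):
                start = offset + len(sent)
                sent += surface
                mention_counter += 1
                sent_mentions.append(
                    EntityMention(
                        start, start + len(surface), etype, surface,
                        mention_id=f"T{len(mentions) + len(sent_mentions) + 1}",
                        concept_id=cid,
                    )
                )
                counts["abbreviated"] += int(abbreviated)
                counts["misspelled"] += int(misspelled)
                sent += pieces[piece_idx + 1]
            # nested inner mention: single first token of a multi-token surface
            for m in list(sent_mentions):
                if m.concept_id in nested_inner_type and " " in m.surface:
                    first_tok = m.surface.split()[0]
                    sent_mentions.append(
                        EntityMention(
                            m.start, m.start + len(first_tok),
                            nested_inner_type[m.concept_id], first_tok,
                            mention_id=f"T{len(mentions) + len(sent_mentions) + 1}",
                        )
                    )
                    counts["nested"] += 1
            mentions.extend(sent_mentions)
            counts["mentions"] += len(sent_mentions)
            counts["sentences"] += 1
            text_parts.append(sent)
            offset += len(sent) + 1  # the joining space
        text = " ".join(text_parts)
        doc = AnnotatedDocument(Document(doc_id, text), sorted(mentions))
        documents.append(doc)
        counts["documents"] += 1
        for s_idx, tokens in enumerate(tokenize_document(text)):
            seq = encode(tokens, doc.mentions, schema)
            tagged.append(TaggedSentence(doc_id, s_idx, seq))

    manifest = {"spec": asdict(spec), "counts": counts}
    return SyntheticCorpus(
        documents, tagged, dictionary, abbreviations,
        {cid: concept_type[cid] for cid in concept_ids}, manifest,
    )
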