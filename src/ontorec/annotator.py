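"""Dictionary-based concept recognizer.

Matches every preferred name and synonym of every class in a pool of
ontologies against the input, token by token, and returns *all* matches —
including overlapping spans and multiple classes on the same span.  The
downstream criteria need the full annotation set: coverage and detail work
on an overlap-resolved selection, while specialization deliberately counts
every annotation.

Matching is exact on normalized token sequences: case-insensitive,
punctuation-insensitive, whole tokens only, no stemming or lemmatization.
A token is a maximal run of letters/digits; hyphens act as separators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import ContractViolationError
from .model import InputDocument, InputType, Ontology

__all__ = [
    "MatchType",
    "Annotation",
    "Token",
    "normalize_term",
    "annotate",
    "filter_keyword_annotations",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)  # letters/digits; _ and - split


class MatchType(Enum):
    PREF = "PREF"
    SYN = "SYN"


@dataclass(frozen=True)
class Token:
    """A normalized token with its character span in the source string."""

    text: str
    start: int
    end: int


@dataclass(frozen=True)
class Annotation:
    """One match between a text span and an ontology class.

    ``start``/``end`` are 0-based character offsets (half-open) into the
    document's raw text; ``annotated_words`` is the number of
    whitespace-delimited words the span covers, which drives the multi-word
    bonus in the coverage score.
    """

    ontology_acronym: str
    class_id: str
    match_type: MatchType
    start: int
    end: int
    matched_text: str
    annotated_words: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "Annotation") -> bool:
        return self.start < other.end and other.start < self.end


def normalize_term(text: str) -> list[Token]:
    """Case-fold and tokenize, keeping each token's source character span."""
    return [
        Token(m.group(0).casefold(), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def _canonical_key(a: Annotation) -> tuple:
    return (a.start, a.end, a.ontology_acronym, a.class_id, a.match_type.value)


def build_dictionary(
    ontologies: Iterable[Ontology],
) -> dict[tuple[str, ...], list[tuple[str, str, MatchType]]]:
    """Map normalized token tuples to the (acronym, class id, match type)
    entries that carry that term.

    When a class's preferred name and one of its synonyms normalize to the
    same term, only the PREF entry is kept for that class.
    """
    dictionary: dict[tuple[str, ...], list[tuple[str, str, MatchType]]] = {}
    for onto in ontologies:
        for cls in onto:
            pref_key = tuple(t.text for t in normalize_term(cls.pref_label))
            entries: dict[tuple[str, ...], MatchType] = {}
            if pref_key:
                entries[pref_key] = MatchType.PREF
            for syn in cls.synonyms:
                key = tuple(t.text for t in normalize_term(syn))
                if key and key not in entries:  # PREF wins over identical SYN
                    entries[key] = MatchType.SYN
            for key, mtype in entries.items():
                dictionary.setdefault(key, []).append((onto.acronym, cls.id, mtype))
    return dictionary


def _window_annotation(
    raw_text: str,
    tokens: Sequence[Token],
    i: int,
    j: int,
    entry: tuple[str, str, MatchType],
) -> Annotation:
    start, end = tokens[i].start, tokens[j - 1].end
    span_text = raw_text[start:end]
    return Annotation(
        ontology_acronym=entry[0],
        class_id=entry[1],
        match_type=entry[2],
        start=start,
        end=end,
        matched_text=span_text,
        annotated_words=max(1, len(span_text.split())),
    )


def annotate(doc: InputDocument, ontologies: list[Ontology]) -> list[Annotation]:
    """Return every token-window match of any dictionary term in ``doc``.

    Every occurrence of every term is reported (term frequency matters to
    coverage), and nested/overlapping matches from different terms are all
    kept.  The result is in canonical order: (start, end, ontology,
    class_id, match_type).
    """
    dictionary = build_dictionary(ontologies)
    if not dictionary:
        return []
    max_len = max(len(k) for k in dictionary)
    tokens = normalize_term(doc.raw_text)
    out: list[Annotation] = []
    for i in range(len(tokens)):
        for j in range(i + 1, min(i + max_len, len(tokens)) + 1):
            key = tuple(t.text for t in tokens[i:j])
            for entry in dictionary.get(key, ()):
                out.append(_window_annotation(doc.raw_text, tokens, i, j, entry))
    out.sort(key=_canonical_key)
    return out


def filter_keyword_annotations(
    annotations: list[Annotation], doc: InputDocument
) -> list[Annotation]:
    """Keep only annotations that cover all words of exactly one keyword.

    In keyword mode the comma boundaries carry term-boundary information:
    a partial match of a multi-word keyword, or a match straddling two
    keywords, is discarded outright.
    """
    if doc.input_type is not InputType.KEYWORDS:
        raise ContractViolationError(
            "filter_keyword_annotations requires a KEYWORDS document"
        )
    keyword_tokens = [
        (kw, normalize_term(doc.raw_text[kw.start : kw.end])) for kw in doc.keywords
    ]
    kept: list[Annotation] = []
    for a in annotations:
        full_matches = 0
        for kw, toks in keyword_tokens:
            if a.start < kw.start or a.end > kw.end:
                continue  # extends outside this keyword
            if all(a.start <= kw.start + t.start and kw.start + t.end <= a.end for t in toks):
                full_matches += 1
        if full_matches == 1:
            kept.append(a)
    return kept
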