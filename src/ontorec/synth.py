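"""Seeded synthetic repository generator.

Builds a small on-disk world the recommender can run against end to end: a
shared term vocabulary with controlled overlap between ontologies,
dictionary files whose classes carry random synonym/definition/property
counts and parent chains, a repository-metadata table with random presence
flags and visit counts, free-text documents salted with vocabulary terms,
and a keyword file.  The same seed always produces byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import ConfigurationError
from .model import Ontology, OntologyClass, compute_depths, write_dictionary

__all__ = ["SynthParams", "generate_synthetic_repository"]

_SYLLABLES = [
    "ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "ne",
    "pa", "qui", "ro", "su", "ti", "vo", "xa", "ze", "bru", "cla",
]

_REPOSITORIES = [("BIOPORTAL", 0.5, 0.5), ("UMLS", 0.3, 0.3), ("OBOFOUNDRY", 0.2, 0.2)]


@dataclass(frozen=True)
class SynthParams:
    """Generator knobs.

    Defaults describe a modest desk-scale repository: 5 ontologies drawing
    40 terms each from a 200-term vocabulary, 30% of terms multi-word, 30%
    of each ontology's terms shared across all ontologies, hierarchies up to
    depth 8, and 120-word documents with roughly half their words drawn
    from the vocabulary.
    """

    n_ontologies: int = 5
    vocab_size: int = 200
    terms_per_ontology: int = 40
    multiword_fraction: float = 0.3
    depth_max: int = 8
    corpus_length: int = 120
    n_documents: int = 3
    vocab_overlap: float = 0.3

    def validate(self) -> None:
        for name in ("n_ontologies", "vocab_size", "terms_per_ontology",
                     "depth_max", "corpus_length", "n_documents"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("multiword_fraction", "vocab_overlap"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.terms_per_ontology > self.vocab_size:
            raise ConfigurationError("terms_per_ontology cannot exceed vocab_size")


def _pseudo_word(rng: random.Random, used: set[str]) -> str:
    while True:
        w = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 4)))
        if w not in used:
            used.add(w)
            return w


def _build_vocabulary(rng: random.Random, params: SynthParams, used: set[str]) -> list[str]:
    base = [_pseudo_word(rng, used) for _ in range(params.vocab_size)]
    n_multi = round(params.multiword_fraction * params.vocab_size)
    terms: list[str] = []
    for i in range(params.vocab_size):
        if i < n_multi:
            partner = rng.choice(base)
            terms.append(f"{base[i]} {partner}")
        else:
            terms.append(base[i])
    return terms


def _build_ontology(
    rng: random.Random,
    acronym: str,
    terms: list[str],
    vocabulary: list[str],
    params: SynthParams,
    used: set[str],
) -> Ontology:
    classes: dict[str, OntologyClass] = {}
    ids: list[str] = []
    for i, term in enumerate(terms, start=1):
        cid = f"{acronym}:{i:05d}"
        synonyms = [_pseudo_word(rng, used) for _ in range(rng.randint(0, 5))]
        if rng.random() < 0.2:
            # occasionally alias another vocabulary term: creates the
            # duplicate-span matches that overlap resolution must handle
            synonyms.append(rng.choice(vocabulary))
        eligible = [c for c in ids if classes[c].depth < params.depth_max]
        parents = [rng.choice(eligible)] if ids and eligible and rng.random() < 0.85 else []
        cls = OntologyClass(
            id=cid,
            pref_label=term,
            synonyms=synonyms,
            definition_count=rng.randint(0, 2),
            property_count=rng.randint(0, 15),
            parents=parents,
        )
        cls.depth = classes[parents[0]].depth + 1 if parents else 1
        classes[cid] = cls
        ids.append(cid)
    return compute_depths(Ontology(acronym=acronym, classes=classes))


def generate_synthetic_repository(
    out_dir: str | Path,
    seed: int,
    params: SynthParams = SynthParams(),
) -> dict:
    """Write a synthetic repository under ``out_dir`` and return a manifest.

    Produces ``ONT<i>.dict`` dictionary files, ``metadata.tsv``,
    ``doc<i>.txt`` free-text documents, ``keywords.txt`` and
    ``manifest.json``.  All randomness flows from ``seed``; parameters are
    validated before any file is written.
    """
    params.validate()
    out = Path(out_dir)
    rng = random.Random(seed)
    used: set[str] = set()

    vocabulary = _build_vocabulary(rng, params, used)
    shared_count = round(params.vocab_overlap * params.terms_per_ontology)
    shared = vocabulary[:shared_count]
    remaining = vocabulary[shared_count:]

    ontologies: list[Ontology] = []
    for i in range(1, params.n_ontologies + 1):
        own = rng.sample(remaining, params.terms_per_ontology - shared_count)
        ontologies.append(
            _build_ontology(rng, f"ONT{i}", shared + own, vocabulary, params, used)
        )

    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    for onto in ontologies:
        name = f"{onto.acronym}.dict"
        write_dictionary(onto, out / name)
        files.append(name)

    lines = ["#repositories"]
    for repo, wp, wv in _REPOSITORIES:
        lines.append(f"{repo}\t{wp}\t{wv}")
    lines += ["", "#ontologies"]
    for onto in ontologies:
        presence = [str(int(rng.random() < 0.7)) for _ in _REPOSITORIES]
        visits = [str(rng.randint(0, 5000)) for _ in _REPOSITORIES]
        lines.append("\t".join([onto.acronym, *presence, *visits]))
    (out / "metadata.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    files.append("metadata.tsv")

    term_pool = sorted({t for o in ontologies for t in (c.pref_label for c in o)})
    for d in range(1, params.n_documents + 1):
        words: list[str] = []
        while len(words) < params.corpus_length:
            if rng.random() < 0.5:
                words.extend(rng.choice(term_pool).split())
            else:
                words.append(_pseudo_word(rng, used))
        name = f"doc{d}.txt"
        (out / name).write_text(" ".join(words[: params.corpus_length]) + "\n", encoding="utf-8")
        files.append(name)

    keywords = rng.sample(term_pool, min(10, len(term_pool)))
    (out / "keywords.txt").write_text(", ".join(keywords) + "\n", encoding="utf-8")
    files.append("keywords.txt")

    manifest = {"seed": seed, "params": asdict(params), "files": sorted(files)}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
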