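import random

import pytest

from ontorec import (
    Annotation,
    MatchType,
    Ontology,
    OntologyClass,
    compute_depths,
    worked_examples,
)


@pytest.fixture()
def blood_cell():
    return worked_examples()["blood_cell"]


@pytest.fixture()
def penicillin():
    return worked_examples()["penicillin"]


def make_annotation(
    start,
    end,
    match_type=MatchType.PREF,
    words=1,
    acronym="ONT",
    class_id="ONT:1",
):
    """Directly build an annotation for scorer-level tests (no document)."""
    return Annotation(
        ontology_acronym=acronym,
        class_id=class_id,
        match_type=match_type,
        start=start,
        end=end,
        matched_text="x" * (end - start),
        annotated_words=words,
    )


def random_annotations(rng: random.Random, n: int, acronym="ONT") -> list[Annotation]:
    """Random annotations over a 40-token grid (4 chars per token)."""
    out = []
    for k in range(n):
        i = rng.randrange(0, 38)
        w = rng.randint(1, 3)
        out.append(
            make_annotation(
                start=4 * i,
                end=4 * (i + w) - 1,
                match_type=rng.choice([MatchType.PREF, MatchType.SYN]),
                words=w,
                acronym=acronym,
                class_id=f"{acronym}:{k}",
            )
        )
    return out


def toy_ontology(acronym: str, labels: dict[str, tuple[str, list[str]]]) -> Ontology:
    """Build an ontology from {class_id: (pref_label, synonyms)}."""
    classes = {
        cid: OntologyClass(id=cid, pref_label=label, synonyms=syns)
        for cid, (label, syns) in labels.items()
    }
    return compute_depths(Ontology(acronym=acronym, classes=classes))
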