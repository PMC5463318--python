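"""Small built-in example scenarios.

Two classic recommendation scenarios are constructed entirely in code:

* ``blood_cell`` — the sentence *"A thrombocyte is a kind of blood cell"*
  against a six-class SNOMEDCT-style toy ontology.  It exercises overlap
  resolution: the multi-word match *blood cell* beats the nested *blood*
  and *cell* matches, and a preferred-name match on *cell* beats the
  synonym matches on the same span.
* ``penicillin`` — the sentence *"Penicillin is an antibiotic used to treat
  tonsillitis"* against two partial dictionaries: O1, a large (declared
  120,000-class) ontology with well-documented classes for *penicillin* and
  *antibiotic*, and O2, a small (800-class) deep ontology covering
  *penicillin* and *tonsillitis*.  It exercises the detail and
  specialization criteria and the set evaluation (O1+O2 jointly cover all
  three terms).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .model import (
    InputDocument,
    InputType,
    Ontology,
    OntologyClass,
    RepositoryMetadata,
    compute_depths,
    make_document,
    write_dictionary,
)
from .scoring import RecommenderConfig

__all__ = ["ExampleFixture", "worked_examples", "write_fixture"]


@dataclass
class ExampleFixture:
    name: str
    document: InputDocument
    ontologies: list[Ontology]
    metadata: RepositoryMetadata | None
    config: RecommenderConfig


def _chain(prefix: str, n: int) -> list[OntologyClass]:
    """A parent chain of n filler classes (labels never match the inputs)."""
    out = []
    for i in range(1, n + 1):
        out.append(
            OntologyClass(
                id=f"{prefix}:{i:04d}",
                pref_label=f"{prefix.lower()} node{i}",
                parents=[] if i == 1 else [f"{prefix}:{i - 1:04d}"],
            )
        )
    return out


def _blood_cell() -> ExampleFixture:
    classes = [
        OntologyClass(id="SCT:0001", pref_label="platelet", synonyms=["thrombocyte"]),
        OntologyClass(id="SCT:0002", pref_label="blood cell"),
        OntologyClass(id="SCT:0003", pref_label="blood"),
        OntologyClass(id="SCT:0004", pref_label="cell structure", synonyms=["cell"]),
        OntologyClass(id="SCT:0005", pref_label="cell"),
        OntologyClass(id="SCT:0006", pref_label="entire cell", synonyms=["cell"]),
    ]
    onto = compute_depths(
        Ontology(acronym="SNOMEDCT", classes={c.id: c for c in classes})
    )
    return ExampleFixture(
        name="blood_cell",
        document=make_document("A thrombocyte is a kind of blood cell"),
        ontologies=[onto],
        metadata=None,
        config=RecommenderConfig(),
    )


def _penicillin() -> ExampleFixture:
    # O1: large, shallow-ish, richly documented classes.
    o1_classes = _chain("O1", 4)  # ancestors of penicillin -> depth 5
    o1_classes.append(
        OntologyClass(
            id="O1:PCN",
            pref_label="penicillin",
            synonyms=["benzylpenicillin", "pcn"],
            definition_count=1,
            property_count=7,
            parents=["O1:0004"],
        )
    )
    o1_classes.extend(_chain("O1A", 2))  # ancestors of antibiotic -> depth 3
    o1_classes.append(
        OntologyClass(
            id="O1:ABX",
            pref_label="antibiotic agent",
            synonyms=[
                "antibiotic",
                "antibacterial",
                "antimicrobial drug",
                "abx",
                "antibiotic substance",
                "bacteriocide",
                "antibiotic compound",
            ],
            definition_count=1,
            property_count=16,
            parents=["O1A:0002"],
        )
    )
    o1 = compute_depths(
        Ontology(
            acronym="O1",
            classes={c.id: c for c in o1_classes},
            declared_size=120_000,
        )
    )

    # O2: small, deep, sparsely documented classes.
    o2_classes = _chain("O2", 5)  # ancestors of penicillin -> depth 6
    o2_classes.append(
        OntologyClass(
            id="O2:PCN",
            pref_label="phenoxymethylpenicillin",
            synonyms=["penicillin"],
            definition_count=0,
            property_count=3,
            parents=["O2:0005"],
        )
    )
    o2_classes.extend(_chain("O2T", 11))  # ancestors of tonsillitis -> depth 12
    o2_classes.append(
        OntologyClass(
            id="O2:TON",
            pref_label="tonsillitis",
            synonyms=[],
            definition_count=0,
            property_count=2,
            parents=["O2T:0011"],
        )
    )
    o2 = compute_depths(
        Ontology(acronym="O2", classes={c.id: c for c in o2_classes}, declared_size=800)
    )

    meta = RepositoryMetadata(
        repositories=["UMLS", "BIOPORTAL"],
        presence_weights={"UMLS": 0.5, "BIOPORTAL": 0.5},
        visits_weights={"UMLS": 0.5, "BIOPORTAL": 0.5},
        presence={
            ("O1", "UMLS"): 1,
            ("O1", "BIOPORTAL"): 1,
            ("O2", "UMLS"): 0,
            ("O2", "BIOPORTAL"): 1,
        },
        visits={
            ("O1", "UMLS"): 4000,
            ("O1", "BIOPORTAL"): 2500,
            ("O2", "UMLS"): 0,
            ("O2", "BIOPORTAL"): 500,
        },
    )
    return ExampleFixture(
        name="penicillin",
        document=make_document("Penicillin is an antibiotic used to treat tonsillitis"),
        ontologies=[o1, o2],
        metadata=meta,
        config=RecommenderConfig(),
    )


def worked_examples() -> dict[str, ExampleFixture]:
    """All built-in example scenarios, keyed by name."""
    fixtures = [_blood_cell(), _penicillin()]
    return {f.name: f for f in fixtures}


def write_fixture(fixture: ExampleFixture, out_dir: str | Path) -> None:
    """Materialize a fixture on disk: input.txt, one dictionary file per
    ontology, and metadata.tsv when the fixture carries repository data."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "input.txt").write_text(fixture.document.raw_text + "\n", encoding="utf-8")
    for onto in fixture.ontologies:
        write_dictionary(onto, out / f"{onto.acronym}.dict")
    if fixture.metadata is not None:
        m = fixture.metadata
        lines = ["#repositories"]
        for r in m.repositories:
            lines.append(f"{r}\t{m.presence_weights[r]}\t{m.visits_weights[r]}")
        lines.append("")
        lines.append("#ontologies")
        acronyms = sorted({acr for acr, _ in m.presence})
        for acr in acronyms:
            row = [acr]
            row += [str(m.presence_of(acr, r)) for r in m.repositories]
            row += [str(m.visits_of(acr, r)) for r in m.repositories]
            lines.append("\t".join(row))
        (out / "metadata.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
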