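"""Domain model: ontologies, classes, repository metadata and input documents.

An :class:`Ontology` is a flat collection of :class:`OntologyClass` records
connected by ``is_a`` parent links.  Class depth (1 = root level) is derived
from those links and feeds the specialization criterion, which rewards
matches on granular classes.  Ontologies can be read from OBO flat files or
from a simple tab-separated dictionary dialect that also carries the
definition/synonym/property counts used by the detail criterion.

Repository metadata — which repositories list an ontology, and how often its
pages were visited recently — feeds the acceptance criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

from .errors import (
    ConfigurationError,
    DanglingParentError,
    FormatError,
    StructuralError,
)

__all__ = [
    "OntologyClass",
    "Ontology",
    "RepositoryMetadata",
    "InputType",
    "InputDocument",
    "Keyword",
    "load_obo",
    "load_dictionary",
    "write_dictionary",
    "compute_depths",
    "load_repository_metadata",
    "make_document",
]

# OBO tags that are not counted as "other properties" of a class.
_OBO_NON_PROPERTY_TAGS = frozenset(
    {"name", "def", "synonym", "is_a", "is_obsolete", "id"}
)


@dataclass
class OntologyClass:
    """One ontology class with the lexical and structural attributes the
    recommender consumes.

    ``depth`` is 1-based: a class with no parents sits at depth 1 (the root
    level).  ``definition_count`` is |D|, ``len(synonyms)`` is |S| and
    ``property_count`` is |P| in the detail criterion.
    """

    id: str
    pref_label: str
    synonyms: list[str] = field(default_factory=list)
    definition_count: int = 0
    property_count: int = 0
    parents: list[str] = field(default_factory=list)
    depth: int = 1

    def __post_init__(self) -> None:
        self.pref_label = " ".join(self.pref_label.split())
        if not self.pref_label:
            raise FormatError(f"class {self.id!r} has an empty preferred label")
        if self.definition_count < 0 or self.property_count < 0:
            raise FormatError(f"class {self.id!r} has negative counts")
        # deduplicate synonyms case-insensitively, order-preserving
        seen: set[str] = set()
        unique: list[str] = []
        for s in self.synonyms:
            key = s.casefold()
            if key not in seen:
                seen.add(key)
                unique.append(s)
        self.synonyms = unique


@dataclass
class Ontology:
    """A named collection of classes.

    ``declared_size`` is |o|, the total number of classes the ontology is
    stated to contain.  It defaults to the number of loaded classes but may
    be larger for partial dictionaries, where only the classes relevant to a
    document are materialized.
    """

    acronym: str
    classes: dict[str, OntologyClass]
    declared_size: int | None = None

    def __post_init__(self) -> None:
        self.acronym = self.acronym.strip().upper()
        if not self.acronym:
            raise FormatError("ontology acronym must be non-empty")
        if not self.classes:
            raise FormatError(
                f"ontology {self.acronym}: an ontology must contain >= 1 class"
            )
        if self.declared_size is None:
            self.declared_size = len(self.classes)
        if self.declared_size < 1 or self.declared_size < len(self.classes):
            raise FormatError(
                f"ontology {self.acronym}: declared_size {self.declared_size} "
                f"is smaller than the {len(self.classes)} loaded classes"
            )
        for cls in self.classes.values():
            for pid in cls.parents:
                if pid not in self.classes:
                    raise DanglingParentError(
                        f"ontology {self.acronym}: class {cls.id!r} references "
                        f"unknown parent {pid!r}"
                    )

    def __iter__(self):
        return iter(self.classes.values())

    def __len__(self) -> int:
        return len(self.classes)


def compute_depths(ontology: Ontology) -> Ontology:
    """Assign each class its 1-based hierarchy depth, in place.

    Depth is 1 plus the length of the shortest parent-path to any root;
    classes without parents are roots at depth 1.  Using the shortest path
    makes depth deterministic and order-independent for classes with
    multiple parents.  Raises :class:`StructuralError` if the parent links
    contain a cycle.
    """
    g = nx.DiGraph()  # edges parent -> child
    g.add_nodes_from(ontology.classes)
    for cls in ontology:
        for pid in cls.parents:
            g.add_edge(pid, cls.id)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
        raise StructuralError(
            f"ontology {ontology.acronym}: cycle in parent links: {path}"
        )
    roots = [cid for cid, cls in ontology.classes.items() if not cls.parents]
    dist = nx.multi_source_dijkstra_path_length(g, roots) if roots else {}
    for cls in ontology:
        cls.depth = int(dist[cls.id]) + 1
    return ontology


# ---------------------------------------------------------------------------
# OBO reader


def _as_list(value) -> list:
    if value is None:
        return []
    return value if isinstance(value, list) else [value]


def _obo_synonym_text(line: str) -> str:
    """Extract the quoted synonym text from an OBO synonym tag value."""
    if line.startswith('"'):
        end = line.find('"', 1)
        if end > 0:
            return line[1:end]
    return line.split("EXACT")[0].split("RELATED")[0].strip().strip('"')


def load_obo(path: str | Path) -> Ontology:
    """Read an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Non-obsolete ``[Term]`` stanzas become classes; ``name`` becomes the
    preferred label, ``synonym`` lines the synonyms, ``def`` lines are
    counted into ``definition_count``, ``is_a`` targets become parents, and
    every other tag-value line on the stanza is counted into
    ``property_count``.  Terms without a name are skipped.  The acronym is
    taken from the ``ontology`` header if present, else the file stem.
    """
    path = Path(path)
    graph = obonet.read_obo(path, ignore_obsolete=True)
    acronym = (graph.graph.get("ontology") or path.stem).upper()
    classes: dict[str, OntologyClass] = {}
    dangling: set[str] = set()
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            dangling.add(node)  # referenced by is_a but never defined
            continue
        synonyms = [_obo_synonym_text(s) for s in _as_list(data.get("synonym"))]
        prop_count = sum(
            len(_as_list(v))
            for k, v in data.items()
            if k not in _OBO_NON_PROPERTY_TAGS
        )
        classes[node] = OntologyClass(
            id=node,
            pref_label=data["name"],
            synonyms=synonyms,
            definition_count=len(_as_list(data.get("def"))),
            property_count=prop_count,
            parents=list(_as_list(data.get("is_a"))),
        )
    for cls in classes.values():
        for pid in cls.parents:
            if pid in dangling:
                raise DanglingParentError(
                    f"{path}: class {cls.id!r} references parent {pid!r} "
                    "which is not defined in the file"
                )
    onto = Ontology(acronym=acronym, classes=classes)
    return compute_depths(onto)


# ---------------------------------------------------------------------------
# Dictionary dialect
#
# Header of key=value lines (acronym=..., optional declared_size=...), a
# blank line, then one tab-separated record per class:
#   id <TAB> pref_label <TAB> syn1|syn2 <TAB> n_defs <TAB> n_props <TAB> p1|p2
# Synonym and parent fields may be empty.  UTF-8, LF line endings.


def load_dictionary(path: str | Path) -> Ontology:
    """Read the line-oriented dictionary dialect into an :class:`Ontology`."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    header: dict[str, str] = {}
    classes: dict[str, OntologyClass] = {}
    in_header = True
    for lineno, line in enumerate(text.splitlines(), start=1):
        if in_header:
            if not line.strip():
                in_header = False
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value header line")
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise FormatError(
                f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}"
            )
        cid, label, syns, ndef, nprop, parents = parts
        if not label.strip():
            raise FormatError(f"{path}:{lineno}: missing pref_label")
        if cid in classes:
            raise FormatError(f"{path}:{lineno}: duplicate class id {cid!r}")
        try:
            definition_count = int(ndef)
            property_count = int(nprop)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer count") from exc
        classes[cid] = OntologyClass(
            id=cid,
            pref_label=label,
            synonyms=[s for s in syns.split("|") if s],
            definition_count=definition_count,
            property_count=property_count,
            parents=[p for p in parents.split("|") if p],
        )
    if "acronym" not in header:
        raise FormatError(f"{path}: missing acronym= header")
    declared = header.get("declared_size")
    onto = Ontology(
        acronym=header["acronym"],
        classes=classes,
        declared_size=int(declared) if declared is not None else None,
    )
    return compute_depths(onto)


def write_dictionary(ontology: Ontology, path: str | Path) -> None:
    """Write an :class:`Ontology` in the dictionary dialect (LF, UTF-8)."""
    lines = [f"acronym={ontology.acronym}", f"declared_size={ontology.declared_size}", ""]
    for cid in sorted(ontology.classes):
        cls = ontology.classes[cid]
        lines.append(
            "\t".join(
                [
                    cls.id,
                    cls.pref_label,
                    "|".join(cls.synonyms),
                    str(cls.definition_count),
                    str(cls.property_count),
                    "|".join(cls.parents),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Repository metadata


@dataclass
class RepositoryMetadata:
    """Per-repository presence flags and visit counts for each ontology.

    ``presence_weights`` (w_p_i) and ``visits_weights`` (w_v_i) each sum to
    one over the ordered repository list.  Ontologies absent from the table
    default to presence 0 and visits 0 everywhere.
    """

    repositories: list[str]
    presence_weights: dict[str, float]
    visits_weights: dict[str, float]
    presence: dict[tuple[str, str], int] = field(default_factory=dict)
    visits: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, weights in (
            ("presence", self.presence_weights),
            ("visits", self.visits_weights),
        ):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{name} weights sum to {total}, expected 1"
                )
            if any(w < 0 for w in weights.values()):
                raise ConfigurationError(f"negative {name} weight")
        for (acr, repo), flag in self.presence.items():
            if flag not in (0, 1):
                raise FormatError(
                    f"presence of {acr} in {repo} is {flag}, must be 0 or 1"
                )
        for (acr, repo), count in self.visits.items():
            if count < 0:
                raise FormatError(f"negative visits for {acr} in {repo}")

    def presence_of(self, acronym: str, repo: str) -> int:
        return self.presence.get((acronym.upper(), repo), 0)

    def visits_of(self, acronym: str, repo: str) -> int:
        return self.visits.get((acronym.upper(), repo), 0)

    def max_visits(self, acronyms: Iterable[str] | None = None) -> dict[str, int]:
        """Highest visit count per repository over a pool of ontologies
        (all known ontologies when ``acronyms`` is None)."""
        if acronyms is None:
            pool = {acr for acr, _ in self.visits}
        else:
            pool = {a.upper() for a in acronyms}
        return {
            repo: max((self.visits_of(a, repo) for a in pool), default=0)
            for repo in self.repositories
        }


def load_repository_metadata(path: str | Path) -> RepositoryMetadata:
    """Read the tab-separated repository-metadata dialect.

    First block: one line per repository — ``name <TAB> w_p <TAB> w_v``.
    Blank line.  Second block: one line per ontology —
    ``acronym <TAB> presence_1 .. presence_n <TAB> visits_1 .. visits_n``
    with repositories in first-block order.
    """
    path = Path(path)
    blocks: list[list[str]] = [[]]
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            continue
        if not line.strip():
            if blocks[-1]:
                blocks.append([])
            continue
        blocks[-1].append(line)
    if not blocks[-1]:
        blocks.pop()
    if len(blocks) < 1:
        raise FormatError(f"{path}: empty metadata file")
    repos: list[str] = []
    w_p: dict[str, float] = {}
    w_v: dict[str, float] = {}
    for line in blocks[0]:
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: repository line needs 3 fields: {line!r}")
        name, wp, wv = parts
        repos.append(name)
        w_p[name] = float(wp)
        w_v[name] = float(wv)
    presence: dict[tuple[str, str], int] = {}
    visits: dict[tuple[str, str], int] = {}
    n = len(repos)
    for line in blocks[1] if len(blocks) > 1 else []:
        parts = line.split("\t")
        if len(parts) != 1 + 2 * n:
            raise FormatError(
                f"{path}: ontology line needs {1 + 2 * n} fields: {line!r}"
            )
        acr = parts[0].upper()
        for i, repo in enumerate(repos):
            presence[(acr, repo)] = int(parts[1 + i])
            visits[(acr, repo)] = int(parts[1 + n + i])
    return RepositoryMetadata(
        repositories=repos,
        presence_weights=w_p,
        visits_weights=w_v,
        presence=presence,
        visits=visits,
    )


# ---------------------------------------------------------------------------
# Input documents


class InputType(Enum):
    TEXT = "text"
    KEYWORDS = "keywords"


@dataclass(frozen=True)
class Keyword:
    """One comma-delimited keyword with its character span in the raw text."""

    text: str
    start: int
    end: int


@dataclass
class InputDocument:
    """The text (or comma-delimited keyword list) to recommend ontologies for."""

    raw_text: str
    input_type: InputType = InputType.TEXT
    keywords: list[Keyword] = field(default_factory=list)


def make_document(raw_text: str, input_type: InputType = InputType.TEXT) -> InputDocument:
    """Build an :class:`InputDocument`; keyword mode splits on commas and
    records each keyword's character span (leading/trailing whitespace
    trimmed from the span)."""
    doc = InputDocument(raw_text=raw_text, input_type=input_type)
    if input_type is InputType.KEYWORDS:
        pos = 0
        for chunk in raw_text.split(","):
            start = pos + (len(chunk) - len(chunk.lstrip()))
            text = chunk.strip()
            if text:
                doc.keywords.append(Keyword(text=text, start=start, end=start + len(text)))
            pos += len(chunk) + 1  # skip the comma
    return doc
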