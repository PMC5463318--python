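"""The four ontology-evaluation criteria: coverage, acceptance, detail,
specialization.

Each criterion maps a candidate ontology to a score in [0, 1]:

* **coverage** — how much of the input the ontology annotates.  Every
  annotation gets ``(typeScore + multiWordScore) * annotatedWords`` points
  (PREF 10 / SYN 5, +3 when the match spans more than one word); within
  each overlapping text fragment only the highest-scoring annotation is
  kept; the kept points are normalized by the best achievable over the
  whole candidate pool.
* **acceptance** — community trust, from presence in named repositories and
  recent visit counts (visits normalized per repository to the pool
  maximum).
* **detail** — richness of the matched classes, from their definition,
  synonym and property counts saturated at constants k_d, k_s, k_p, averaged
  over the selected annotations.
* **specialization** — size-penalized, depth-rewarded fit to the input's
  domain, computed over *all* annotations (not just the selected ones) and
  normalized by the pool maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .annotator import Annotation, MatchType
from .errors import ConfigurationError, UndefinedCoverageError
from .model import InputDocument, Ontology, OntologyClass, RepositoryMetadata

__all__ = [
    "RecommenderConfig",
    "SelectionResult",
    "NormalizationContext",
    "load_config",
    "annotation_score_v2",
    "select_annotations",
    "coverage",
    "max_coverage_points",
    "acceptance",
    "detail_annotation",
    "detail",
    "specialization_raw",
    "specialization",
]


@dataclass(frozen=True)
class RecommenderConfig:
    """All weights and constants of the recommender.

    The four criterion weights sum to 1; coverage dominates by default
    (0.55) because high input coverage is the primary requirement, with
    acceptance, detail and specialization at 0.15 each.  ``k_d``, ``k_s``,
    ``k_p`` are the definition/synonym/property counts at which the detail
    sub-scores saturate.  The legacy scorer uses its own PREF/SYN constants
    and a configurable depth base (0 = root at level 0).
    """

    w_c: float = 0.55
    w_a: float = 0.15
    w_d: float = 0.15
    w_s: float = 0.15
    w_presence: float = 0.5
    w_visits: float = 0.5
    pref_score_v2: float = 10.0
    syn_score_v2: float = 5.0
    multiword_bonus: float = 3.0
    pref_score_v1: float = 10.0
    syn_score_v1: float = 8.0
    k_d: float = 1.0
    k_s: float = 4.0
    k_p: float = 10.0
    max_set_size: int = 3
    depth_base: int = 0

    def __post_init__(self) -> None:
        if abs(self.w_c + self.w_a + self.w_d + self.w_s - 1.0) > 1e-9:
            raise ConfigurationError("criterion weights w_c+w_a+w_d+w_s must sum to 1")
        if abs(self.w_presence + self.w_visits - 1.0) > 1e-9:
            raise ConfigurationError("w_presence + w_visits must sum to 1")
        if min(self.w_c, self.w_a, self.w_d, self.w_s, self.w_presence, self.w_visits) < 0:
            raise ConfigurationError("weights must be non-negative")
        for name in ("pref_score_v2", "syn_score_v2", "multiword_bonus",
                     "pref_score_v1", "syn_score_v1", "k_d", "k_s", "k_p"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"constant {name} must be strictly positive")
        if self.max_set_size < 2:
            raise ConfigurationError("max_set_size must be >= 2")
        if self.depth_base not in (0, 1):
            raise ConfigurationError("depth_base must be 0 or 1")


def load_config(path) -> RecommenderConfig:
    """Read a key-value (YAML) configuration file; unknown keys rejected.

    A ``weights: [c, a, d, s]`` shorthand is accepted alongside the
    individual ``w_c`` .. ``w_s`` keys.
    """
    data = yaml.safe_load(open(path, encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of option keys")
    if "weights" in data:
        w = data.pop("weights")
        if len(w) != 4:
            raise ConfigurationError("weights shorthand needs 4 values (c, a, d, s)")
        data.update(zip(("w_c", "w_a", "w_d", "w_s"), w))
    valid = RecommenderConfig.__dataclass_fields__
    unknown = set(data) - set(valid)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    return RecommenderConfig(**data)


@dataclass
class SelectionResult:
    """Outcome of overlap resolution: a non-overlapping subset of
    annotations and the total coverage points they carry."""

    selected: list[Annotation]
    discarded: list[Annotation]
    raw_coverage_points: float


@dataclass
class NormalizationContext:
    """Pool-level maxima that map raw criterion values onto [0, 1].

    All maxima are computed over the candidate pool of the current run, so a
    score of 1 always means "best among the candidates considered here".
    """

    max_coverage_points: float
    max_specialization_raw: float
    max_visits: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Coverage


def annotation_score_v2(a: Annotation, cfg: RecommenderConfig = RecommenderConfig()) -> float:
    """Score of one annotation: (typeScore + multiWordScore) * annotatedWords."""
    type_score = cfg.pref_score_v2 if a.match_type is MatchType.PREF else cfg.syn_score_v2
    multiword = cfg.multiword_bonus if a.annotated_words > 1 else 0.0
    return (type_score + multiword) * a.annotated_words


def _selection_sort_key(a: Annotation, cfg: RecommenderConfig):
    # score desc, PREF before SYN, longer span, smaller start, class id, acronym
    return (
        -annotation_score_v2(a, cfg),
        0 if a.match_type is MatchType.PREF else 1,
        -(a.end - a.start),
        a.start,
        a.class_id,
        a.ontology_acronym,
    )


def select_annotations(
    annotations: list[Annotation], cfg: RecommenderConfig = RecommenderConfig()
) -> SelectionResult:
    """Resolve overlaps: per overlapping text fragment keep only the
    highest-scoring annotation.

    Greedy sweep in descending score order with deterministic tie-breaking
    (PREF over SYN, longer span, smaller start, class id, acronym); an
    annotation is kept iff it overlaps no already-kept annotation.
    """
    ordered = sorted(annotations, key=lambda a: _selection_sort_key(a, cfg))
    selected: list[Annotation] = []
    discarded: list[Annotation] = []
    for a in ordered:
        if any(a.overlaps(s) for s in selected):
            discarded.append(a)
        else:
            selected.append(a)
    selected.sort(key=lambda a: (a.start, a.end))
    points = sum(annotation_score_v2(a, cfg) for a in selected)
    return SelectionResult(selected=selected, discarded=discarded, raw_coverage_points=points)


def max_coverage_points(
    all_annotations: list[Annotation], cfg: RecommenderConfig = RecommenderConfig()
) -> float:
    """Best selected points over the pooled annotations of every candidate."""
    return select_annotations(all_annotations, cfg).raw_coverage_points


def coverage(
    o: Ontology,
    doc: InputDocument,
    annotations: list[Annotation],
    ctx: NormalizationContext,
    cfg: RecommenderConfig = RecommenderConfig(),
) -> float:
    """Normalized coverage of ``doc`` by ``o``: selected points divided by
    the pool maximum."""
    if ctx.max_coverage_points <= 0:
        raise UndefinedCoverageError(
            "no candidate ontology annotates the input; coverage is undefined"
        )
    points = select_annotations(annotations, cfg).raw_coverage_points
    return points / ctx.max_coverage_points


# ---------------------------------------------------------------------------
# Acceptance


def acceptance(
    o: Ontology,
    meta: RepositoryMetadata,
    ctx: NormalizationContext,
    cfg: RecommenderConfig = RecommenderConfig(),
) -> float:
    """w_presence * presenceScore + w_visits * visitsScore.

    presenceScore is the weighted sum of per-repository presence flags;
    visitsScore weights per-repository visit counts normalized by the pool
    maximum for that repository (0 when the pool maximum is 0).
    """
    presence_score = sum(
        meta.presence_weights[r] * meta.presence_of(o.acronym, r)
        for r in meta.repositories
    )
    visits_score = 0.0
    for r in meta.repositories:
        mx = ctx.max_visits.get(r, 0)
        if mx > 0:
            visits_score += meta.visits_weights[r] * (meta.visits_of(o.acronym, r) / mx)
    return cfg.w_presence * presence_score + cfg.w_visits * visits_score


# ---------------------------------------------------------------------------
# Detail


def detail_annotation(
    a: Annotation, cls: OntologyClass, cfg: RecommenderConfig = RecommenderConfig()
) -> float:
    """Mean of the saturated definition/synonym/property sub-scores of the
    matched class."""
    d = min(cls.definition_count / cfg.k_d, 1.0)
    s = min(len(cls.synonyms) / cfg.k_s, 1.0)
    p = min(cls.property_count / cfg.k_p, 1.0)
    return (d + s + p) / 3.0


def detail(
    o: Ontology, selection: SelectionResult, cfg: RecommenderConfig = RecommenderConfig()
) -> float:
    """Mean per-annotation detail over the selected annotations (0 when the
    selection is empty)."""
    if not selection.selected:
        return 0.0
    total = sum(
        detail_annotation(a, o.classes[a.class_id], cfg) for a in selection.selected
    )
    return total / len(selection.selected)


# ---------------------------------------------------------------------------
# Specialization


def specialization_raw(
    o: Ontology, annotations: list[Annotation], cfg: RecommenderConfig = RecommenderConfig()
) -> float:
    """Pre-normalization specialization:
    sum(annotationScore2 + 2 * depth) / log10(|o|) over *all* annotations."""
    if o.declared_size < 2:
        raise ConfigurationError(
            f"ontology {o.acronym}: specialization needs declared_size >= 2"
        )
    total = sum(
        annotation_score_v2(a, cfg) + 2.0 * o.classes[a.class_id].depth
        for a in annotations
    )
    return total / math.log10(o.declared_size)


def specialization(
    o: Ontology,
    annotations: list[Annotation],
    ctx: NormalizationContext,
    cfg: RecommenderConfig = RecommenderConfig(),
) -> float:
    """Specialization normalized to [0, 1] by the pool maximum raw value."""
    if ctx.max_specialization_raw <= 0:
        return 0.0
    return specialization_raw(o, annotations, cfg) / ctx.max_specialization_raw
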