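"""Evaluation of ontology sets.

A single ontology rarely covers a whole biomedical input; combinations of
2..max_set_size ontologies are enumerated, pruned when they cannot improve
on their parts, and scored jointly.  The set's coverage comes from overlap
resolution over the pooled annotations; acceptance, detail and
specialization are averages of the members' scores weighted by each
member's contribution to the set's selected coverage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .annotator import Annotation
from .errors import ConfigurationError, OntorecError
from .model import Ontology
from .ranking import CriterionScores, RankedResult, combine
from .scoring import (
    NormalizationContext,
    RecommenderConfig,
    SelectionResult,
    annotation_score_v2,
    select_annotations,
)

__all__ = ["OntologySet", "enumerate_sets", "prune", "coverage_set", "score_set"]


@dataclass
class OntologySet:
    """A candidate combination of 2..max_set_size ontologies.

    ``contributions`` maps each member acronym to its share of the set's
    selected coverage points; the shares sum to 1 whenever the set has any
    selected points.  Each selected annotation is attributed to exactly one
    member — the one that supplied the annotation that won the selection
    tie-break.
    """

    members: tuple[str, ...]
    pooled_annotations: list[Annotation]
    selection: SelectionResult
    contributions: dict[str, float] = field(default_factory=dict)

    def member_points(self, cfg: RecommenderConfig) -> dict[str, float]:
        pts = {m: 0.0 for m in self.members}
        for a in self.selection.selected:
            pts[a.ontology_acronym] += annotation_score_v2(a, cfg)
        return pts


def _fragments(annotations: list[Annotation]) -> frozenset[tuple[int, int]]:
    return frozenset(a.span for a in annotations)


def build_set(
    members: tuple[str, ...],
    annotations_by_ontology: dict[str, list[Annotation]],
    cfg: RecommenderConfig,
) -> OntologySet:
    pooled: list[Annotation] = []
    for m in members:
        pooled.extend(annotations_by_ontology[m])
    selection = select_annotations(pooled, cfg)
    oset = OntologySet(members=members, pooled_annotations=pooled, selection=selection)
    total = selection.raw_coverage_points
    if total > 0:
        oset.contributions = {
            m: pts / total for m, pts in oset.member_points(cfg).items()
        }
    return oset


def prune(
    oset: OntologySet,
    annotations_by_ontology: dict[str, list[Annotation]],
    cfg: RecommenderConfig = RecommenderConfig(),
) -> bool:
    """True when the set should be discarded without full evaluation.

    Two pruning rules: (1) two members cover exactly the same selected text
    fragments, so one of them is redundant; (2) the set's selected coverage
    points do not exceed those of one of its proper subsets (a single
    member, or a smaller combination), i.e. the combination adds no
    coverage.
    """
    member_selections = {
        m: select_annotations(annotations_by_ontology[m], cfg)
        for m in oset.members
    }
    frags = {m: _fragments(sel.selected) for m, sel in member_selections.items()}
    for m1, m2 in combinations(oset.members, 2):
        if frags[m1] == frags[m2]:
            return True
    own = oset.selection.raw_coverage_points
    for size in range(1, len(oset.members)):
        for sub in combinations(oset.members, size):
            if size == 1:
                sub_points = member_selections[sub[0]].raw_coverage_points
            else:
                sub_points = build_set(sub, annotations_by_ontology, cfg).selection.raw_coverage_points
            if own <= sub_points:
                return True
    return False


def enumerate_sets(
    candidates: list[Ontology],
    annotations_by_ontology: dict[str, list[Annotation]],
    cfg: RecommenderConfig = RecommenderConfig(),
) -> list[OntologySet]:
    """All unpruned combinations of 2..max_set_size candidates, in
    deterministic (size, lexicographic) order."""
    if cfg.max_set_size < 2:
        raise ConfigurationError("max_set_size must be >= 2 for set evaluation")
    acronyms = sorted(o.acronym for o in candidates)
    out: list[OntologySet] = []
    for size in range(2, min(cfg.max_set_size, len(acronyms)) + 1):
        for members in combinations(acronyms, size):
            oset = build_set(members, annotations_by_ontology, cfg)
            if not prune(oset, annotations_by_ontology, cfg):
                out.append(oset)
    return out


def coverage_set(
    oset: OntologySet,
    ctx: NormalizationContext,
    cfg: RecommenderConfig = RecommenderConfig(),
) -> float:
    """The set's selected points normalized by the pool maximum."""
    if ctx.max_coverage_points <= 0:
        return 0.0
    return oset.selection.raw_coverage_points / ctx.max_coverage_points


def score_set(
    oset: OntologySet,
    member_scores: dict[str, CriterionScores],
    ctx: NormalizationContext,
    cfg: RecommenderConfig = RecommenderConfig(),
) -> RankedResult:
    """Aggregate a set's criterion scores and relevance.

    Coverage comes from the pooled selection; acceptance, detail and
    specialization are the members' scores weighted by their coverage
    contributions, so an ontology influences the set score in proportion to
    the coverage it supplies.
    """
    if oset.contributions:
        total = sum(oset.contributions.values())
        if abs(total - 1.0) > 1e-9:
            raise OntorecError(
                f"set {oset.members}: contributions sum to {total}, expected 1"
            )
    cov = coverage_set(oset, ctx, cfg)
    acc = det = spec = 0.0
    for m in oset.members:
        c = oset.contributions.get(m, 0.0)
        acc += c * member_scores[m].acceptance
        det += c * member_scores[m].detail
        spec += c * member_scores[m].specialization
    scores = CriterionScores(coverage=cov, acceptance=acc, detail=det, specialization=spec)
    return RankedResult(
        subject=oset.members,
        scores=scores,
        relevance=combine(scores, cfg),
        annotation_count=len(oset.pooled_annotations),
        selected_annotations=list(oset.selection.selected),
    )
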