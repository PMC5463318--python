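"""Relevance aggregation, ranking, the legacy scorer and display scaling."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .annotator import Annotation, MatchType
from .errors import ConfigurationError, ContractViolationError
from .model import InputDocument, Ontology
from .scoring import RecommenderConfig

__all__ = [
    "CriterionScores",
    "RankedResult",
    "combine",
    "rank",
    "score_v1",
    "to_display",
]


@dataclass(frozen=True)
class CriterionScores:
    """The four per-criterion scores of a candidate, each in [0, 1]."""

    coverage: float
    acceptance: float
    detail: float
    specialization: float


@dataclass
class RankedResult:
    """One row of the recommendation output: a single ontology acronym or an
    ordered tuple of acronyms, its criterion scores, aggregated relevance,
    and annotation bookkeeping."""

    subject: str | tuple[str, ...]
    scores: CriterionScores
    relevance: float
    annotation_count: int = 0
    selected_annotations: list[Annotation] = field(default_factory=list)
    rank: int = 0

    @property
    def subject_label(self) -> str:
        if isinstance(self.subject, tuple):
            return ",".join(self.subject)
        return self.subject


def combine(scores: CriterionScores, cfg: RecommenderConfig = RecommenderConfig()) -> float:
    """Weighted aggregation of the four criteria into one relevance score."""
    return (
        cfg.w_c * scores.coverage
        + cfg.w_a * scores.acceptance
        + cfg.w_d * scores.detail
        + cfg.w_s * scores.specialization
    )


def _rank_key(r: RankedResult):
    return (
        -r.relevance,
        -r.scores.coverage,
        -r.scores.acceptance,
        r.subject_label,
    )


def rank(results: list[RankedResult]) -> list[RankedResult]:
    """Sort by relevance descending (ties: coverage, acceptance, then
    acronym) and assign consecutive 1-based ranks."""
    ordered = sorted(results, key=_rank_key)
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def score_v1(
    o: Ontology,
    doc: InputDocument,
    annotations: list[Annotation],
    cfg: RecommenderConfig = RecommenderConfig(),
) -> float:
    """Legacy relevance score: sum(annotationScore + 2 * hierarchyLevel)
    over all annotations, divided by log10(|o|).

    annotationScore is 10 for PREF and 8 for SYN matches; hierarchyLevel is
    depth - 1 under the default 0-based convention (``cfg.depth_base = 0``,
    root at level 0) or the 1-based depth itself when ``depth_base = 1``.
    The raw value is reported un-normalized and is unbounded above, which is
    precisely the behavior the current recommender replaced: many duplicate
    matches on a few terms can outscore broad coverage.
    """
    if o.declared_size < 2:
        raise ConfigurationError(
            f"ontology {o.acronym}: legacy score needs declared_size >= 2"
        )
    total = 0.0
    for a in annotations:
        type_score = cfg.pref_score_v1 if a.match_type is MatchType.PREF else cfg.syn_score_v1
        depth = o.classes[a.class_id].depth
        level = depth if cfg.depth_base == 1 else depth - 1
        total += type_score + 2.0 * level
    return total / math.log10(o.declared_size)


def to_display(score: float) -> float:
    """Map a score from [0, 1] to the [0, 100] display scale, rounded
    half-up to one decimal place."""
    if not 0.0 <= score <= 1.0:
        raise ContractViolationError(f"display score {score} outside [0, 1]")
    scaled = Decimal(str(score)) * 100
    return float(scaled.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
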