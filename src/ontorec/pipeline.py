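"""Run orchestration: load inputs, annotate, score, rank, report.

The full recommendation pipeline is: annotate the input with every
candidate ontology; in keyword mode drop partial matches; discard
ontologies with no annotations (they are irrelevant to the input); compute
the pool-level normalization maxima; score each candidate on the four
criteria; aggregate and rank — either single ontologies or ontology sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotator import Annotation, annotate, filter_keyword_annotations
from .model import (
    InputDocument,
    InputType,
    Ontology,
    RepositoryMetadata,
    load_dictionary,
    load_obo,
    load_repository_metadata,
    make_document,
)
from .ranking import CriterionScores, RankedResult, combine, rank, to_display
from .scoring import (
    NormalizationContext,
    RecommenderConfig,
    acceptance,
    detail,
    max_coverage_points,
    select_annotations,
    specialization_raw,
)
from .sets import enumerate_sets, score_set

__all__ = ["RunReport", "evaluate", "recommend", "load_ontology"]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Self-contained record of one recommendation run.

    Carries the configuration echo and the normalization constants so that
    re-running with the same inputs reproduces identical scores.
    """

    input_type: str
    input_length: int
    output_type: str
    candidates_before_filter: int
    candidates_after_filter: int
    normalization: dict
    results: list[RankedResult]
    config: dict
    status: str = "ok"
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "input": {"type": self.input_type, "length": self.input_length},
            "output_type": self.output_type,
            "candidates": {
                "before_annotation_filter": self.candidates_before_filter,
                "after_annotation_filter": self.candidates_after_filter,
            },
            "normalization": self.normalization,
            "config": self.config,
            "seed": self.seed,
            "results": [
                {
                    "rank": r.rank,
                    "subject": list(r.subject) if isinstance(r.subject, tuple) else r.subject,
                    "relevance": r.relevance,
                    "relevance_display": to_display(r.relevance),
                    "coverage": r.scores.coverage,
                    "acceptance": r.scores.acceptance,
                    "detail": r.scores.detail,
                    "specialization": r.scores.specialization,
                    "annotation_count": r.annotation_count,
                    "selected_annotation_count": len(r.selected_annotations),
                    "selected_annotations": [
                        {
                            "ontology": a.ontology_acronym,
                            "class_id": a.class_id,
                            "match_type": a.match_type.value,
                            "start": a.start,
                            "end": a.end,
                            "text": a.matched_text,
                        }
                        for a in r.selected_annotations
                    ],
                }
                for r in self.results
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        header = (
            "rank\tsubject\trelevance\tcoverage\tacceptance\tdetail\t"
            "specialization\tannotation_count"
        )
        rows = [header]
        for r in self.results:
            rows.append(
                "\t".join(
                    [
                        str(r.rank),
                        r.subject_label,
                        f"{to_display(r.relevance):.1f}",
                        f"{to_display(r.scores.coverage):.1f}",
                        f"{to_display(r.scores.acceptance):.1f}",
                        f"{to_display(r.scores.detail):.1f}",
                        f"{to_display(r.scores.specialization):.1f}",
                        str(r.annotation_count),
                    ]
                )
            )
        return "\n".join(rows) + "\n"


def _config_echo(cfg: RecommenderConfig) -> dict:
    return {f: getattr(cfg, f) for f in RecommenderConfig.__dataclass_fields__}


def build_context(
    candidates: list[Ontology],
    annotations_by_ontology: dict[str, list[Annotation]],
    meta: RepositoryMetadata | None,
    cfg: RecommenderConfig,
) -> NormalizationContext:
    """Compute the pool-level maxima used to normalize raw scores.

    The coverage maximum is the larger of the pooled union selection and the
    best single-candidate selection; the greedy union sweep can in rare
    layouts fall below a single candidate's selection, and taking the max
    keeps every normalized coverage within [0, 1].
    """
    pooled: list[Annotation] = []
    for o in candidates:
        pooled.extend(annotations_by_ontology[o.acronym])
    union_best = max_coverage_points(pooled, cfg)
    per_candidate = [
        select_annotations(annotations_by_ontology[o.acronym], cfg).raw_coverage_points
        for o in candidates
    ]
    mcp = max([union_best, *per_candidate], default=0.0)
    max_spec = max(
        (
            specialization_raw(o, annotations_by_ontology[o.acronym], cfg)
            for o in candidates
        ),
        default=0.0,
    )
    max_visits = (
        meta.max_visits([o.acronym for o in candidates]) if meta is not None else {}
    )
    return NormalizationContext(
        max_coverage_points=mcp,
        max_specialization_raw=max_spec,
        max_visits=max_visits,
    )


def evaluate(
    doc: InputDocument,
    ontologies: list[Ontology],
    meta: RepositoryMetadata | None = None,
    cfg: RecommenderConfig = RecommenderConfig(),
    output: str = "ontologies",
) -> RunReport:
    """Score and rank ``ontologies`` (or their sets) for ``doc``.

    ``output`` is ``"ontologies"`` for single-ontology ranking or ``"sets"``
    for combinations of 2..max_set_size.  Ontologies with no annotations on
    the input are excluded before scoring; when nothing matches at all the
    report carries an empty ranking and an explanatory status.
    """
    if output not in ("ontologies", "sets"):
        raise ValueError(f"unknown output type {output!r}")
    all_annotations = annotate(doc, ontologies)
    if doc.input_type is InputType.KEYWORDS:
        all_annotations = filter_keyword_annotations(all_annotations, doc)
    by_ontology: dict[str, list[Annotation]] = {o.acronym: [] for o in ontologies}
    for a in all_annotations:
        by_ontology[a.ontology_acronym].append(a)
    candidates = [o for o in ontologies if by_ontology[o.acronym]]
    logger.debug(
        "annotation filter: %d/%d candidates retained", len(candidates), len(ontologies)
    )

    report = RunReport(
        input_type=doc.input_type.value,
        input_length=len(doc.raw_text),
        output_type=output,
        candidates_before_filter=len(ontologies),
        candidates_after_filter=len(candidates),
        normalization={},
        results=[],
        config=_config_echo(cfg),
    )
    if not candidates:
        report.status = "no ontology annotates the input; nothing to recommend"
        return report

    ctx = build_context(candidates, by_ontology, meta, cfg)
    report.normalization = {
        "max_coverage_points": ctx.max_coverage_points,
        "max_specialization_raw": ctx.max_specialization_raw,
        "max_visits": dict(ctx.max_visits),
    }

    member_scores: dict[str, CriterionScores] = {}
    singles: list[RankedResult] = []
    for o in candidates:
        anns = by_ontology[o.acronym]
        selection = select_annotations(anns, cfg)
        scores = CriterionScores(
            coverage=selection.raw_coverage_points / ctx.max_coverage_points,
            acceptance=acceptance(o, meta, ctx, cfg) if meta is not None else 0.0,
            detail=detail(o, selection, cfg),
            specialization=(
                specialization_raw(o, anns, cfg) / ctx.max_specialization_raw
                if ctx.max_specialization_raw > 0
                else 0.0
            ),
        )
        member_scores[o.acronym] = scores
        singles.append(
            RankedResult(
                subject=o.acronym,
                scores=scores,
                relevance=combine(scores, cfg),
                annotation_count=len(anns),
                selected_annotations=list(selection.selected),
            )
        )
        logger.debug(
            "%s: coverage=%.4f acceptance=%.4f detail=%.4f specialization=%.4f",
            o.acronym, scores.coverage, scores.acceptance, scores.detail,
            scores.specialization,
        )

    if output == "ontologies":
        report.results = rank(singles)
    else:
        if len(candidates) < 2:
            report.status = (
                "fewer than two ontologies annotate the input; no sets to evaluate"
            )
            return report
        osets = enumerate_sets(candidates, by_ontology, cfg)
        report.results = rank(
            [score_set(s, member_scores, ctx, cfg) for s in osets]
        )
        if not report.results:
            report.status = "all candidate sets were pruned (no combination adds coverage)"
    return report


def load_ontology(path: str | Path) -> Ontology:
    """Load an ontology from an OBO file (.obo) or the dictionary dialect."""
    path = Path(path)
    if path.suffix.lower() == ".obo":
        return load_obo(path)
    return load_dictionary(path)


def recommend(
    input_path: str | Path,
    ontology_paths: list[str | Path],
    metadata_path: str | Path | None = None,
    cfg: RecommenderConfig = RecommenderConfig(),
    input_type: InputType = InputType.TEXT,
    output: str = "ontologies",
) -> RunReport:
    """File-based front door: read the input document, the ontologies and
    the repository metadata, then run :func:`evaluate`."""
    raw = Path(input_path).read_text(encoding="utf-8").strip()
    doc = make_document(raw, input_type)
    ontologies = [load_ontology(p) for p in ontology_paths]
    meta = load_repository_metadata(metadata_path) if metadata_path else None
    return evaluate(doc, ontologies, meta, cfg, output=output)
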