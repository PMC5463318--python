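"""Criterion scorers: annotation scores, overlap resolution, the four criteria."""

import math
import random
from itertools import combinations

import pytest

from ontorec import (
    ConfigurationError,
    MatchType,
    NormalizationContext,
    Ontology,
    OntologyClass,
    RecommenderConfig,
    RepositoryMetadata,
    UndefinedCoverageError,
    acceptance,
    annotate,
    annotation_score_v2,
    compute_depths,
    coverage,
    detail,
    detail_annotation,
    make_document,
    max_coverage_points,
    select_annotations,
    specialization,
    specialization_raw,
)

from conftest import make_annotation, random_annotations

CFG = RecommenderConfig()


class TestAnnotationScore:
    @pytest.mark.parametrize(
        "match_type,words,expected",
        [
            (MatchType.PREF, 2, 26.0),  # (10 + 3) * 2
            (MatchType.SYN, 1, 5.0),
            (MatchType.SYN, 3, 24.0),  # (5 + 3) * 3
            (MatchType.PREF, 1, 10.0),
        ],
    )
    def test_formula(self, match_type, words, expected):
        a = make_annotation(0, 4 * words, match_type, words)
        assert annotation_score_v2(a, CFG) == expected


class TestSelectAnnotations:
    def test_blood_cell_selection(self, blood_cell):
        anns = annotate(blood_cell.document, blood_cell.ontologies)
        sel = select_annotations(anns, CFG)
        assert {a.class_id for a in sel.selected} == {"SCT:0001", "SCT:0002"}
        assert sel.raw_coverage_points == 31.0

    def test_single_annotation_selected(self):
        a = make_annotation(0, 4)
        sel = select_annotations([a], CFG)
        assert sel.selected == [a] and sel.discarded == []

    def test_identical_span_pref_beats_syn(self):
        pref = make_annotation(0, 4, MatchType.PREF, class_id="X:1")
        syn = make_annotation(0, 4, MatchType.SYN, class_id="X:2")
        # exhaustive check: of the two possible single selections, PREF wins
        sel = select_annotations([syn, pref], CFG)
        assert sel.selected == [pref] and sel.discarded == [syn]

    def test_empty_input(self):
        sel = select_annotations([], CFG)
        assert sel.selected == [] and sel.raw_coverage_points == 0.0

    def test_invariants_on_random_instances(self):
        rng = random.Random(7)
        for _ in range(60):
            anns = random_annotations(rng, rng.randint(1, 15))
            sel = select_annotations(anns, CFG)
            # no two selected overlap
            for a, b in combinations(sel.selected, 2):
                assert not a.overlaps(b)
            # every discarded overlaps a selected annotation of >= score
            for d in sel.discarded:
                assert any(
                    d.overlaps(s)
                    and annotation_score_v2(s, CFG) >= annotation_score_v2(d, CFG)
                    for s in sel.selected
                )
            assert sel.raw_coverage_points == pytest.approx(
                sum(annotation_score_v2(a, CFG) for a in sel.selected)
            )
            assert len(sel.selected) + len(sel.discarded) == len(anns)


class TestCoverage:
    def test_self_normalization_single_candidate(self, blood_cell):
        anns = annotate(blood_cell.document, blood_cell.ontologies)
        mcp = max_coverage_points(anns, CFG)
        ctx = NormalizationContext(max_coverage_points=mcp, max_specialization_raw=1.0)
        assert coverage(
            blood_cell.ontologies[0], blood_cell.document, anns, ctx, CFG
        ) == pytest.approx(1.0)

    def test_pool_maximum_via_union_selection(self, blood_cell):
        anns = annotate(blood_cell.document, blood_cell.ontologies)
        assert max_coverage_points(anns, CFG) == 31.0

    def test_disjoint_ontologies_points_add(self):
        a = make_annotation(0, 7, words=2, acronym="A", class_id="A:1")
        b = make_annotation(12, 15, acronym="B", class_id="B:1")
        assert max_coverage_points([a, b], CFG) == annotation_score_v2(
            a, CFG
        ) + annotation_score_v2(b, CFG)

    def test_same_span_takes_best(self):
        a = make_annotation(0, 7, MatchType.PREF, words=2, acronym="A", class_id="A:1")
        b = make_annotation(0, 7, MatchType.PREF, words=1, acronym="B", class_id="B:1")
        assert max_coverage_points([a, b], CFG) == 26.0

    def test_repeated_term_doubles_points(self):
        once = [make_annotation(0, 4)]
        twice = [make_annotation(0, 4), make_annotation(8, 12, class_id="ONT:2")]
        assert max_coverage_points(twice, CFG) == 2 * max_coverage_points(once, CFG)

    def test_zero_pool_maximum_is_an_error(self, blood_cell):
        ctx = NormalizationContext(max_coverage_points=0.0, max_specialization_raw=1.0)
        with pytest.raises(UndefinedCoverageError):
            coverage(blood_cell.ontologies[0], blood_cell.document, [], ctx, CFG)

    def test_adding_a_class_never_decreases_points(self, blood_cell):
        # coverage monotonicity: a new class matching an uncovered fragment
        doc = make_document("thrombocyte plus leucocyte")
        onto = blood_cell.ontologies[0]
        before = select_annotations(annotate(doc, [onto]), CFG).raw_coverage_points
        bigger = dict(onto.classes)
        bigger["SCT:0099"] = OntologyClass(id="SCT:0099", pref_label="leucocyte")
        onto2 = compute_depths(Ontology(acronym=onto.acronym, classes=bigger))
        after = select_annotations(annotate(doc, [onto2]), CFG).raw_coverage_points
        assert after >= before


def _meta(visits_ont=500, visits_max=1000):
    return RepositoryMetadata(
        repositories=["R1"],
        presence_weights={"R1": 1.0},
        visits_weights={"R1": 1.0},
        presence={("ONT", "R1"): 1},
        visits={("ONT", "R1"): visits_ont, ("OTHER", "R1"): visits_max},
    )


class TestAcceptance:
    def _onto(self):
        return Ontology(
            acronym="ONT", classes={"A": OntologyClass(id="A", pref_label="a")}
        )

    def test_upper_bound(self):
        meta = _meta(visits_ont=1000)
        ctx = NormalizationContext(1.0, 1.0, max_visits={"R1": 1000})
        assert acceptance(self._onto(), meta, ctx, CFG) == pytest.approx(1.0)

    def test_lower_bound(self):
        meta = RepositoryMetadata(
            repositories=["R1"],
            presence_weights={"R1": 1.0},
            visits_weights={"R1": 1.0},
        )
        ctx = NormalizationContext(1.0, 1.0, max_visits={"R1": 100})
        assert acceptance(self._onto(), meta, ctx, CFG) == 0.0

    def test_half_visits_of_pool_maximum(self):
        meta = _meta(visits_ont=500, visits_max=1000)
        ctx = NormalizationContext(1.0, 1.0, max_visits={"R1": 1000})
        assert acceptance(self._onto(), meta, ctx, CFG) == pytest.approx(0.75)

    def test_zero_max_visits_contributes_nothing(self):
        meta = _meta(visits_ont=0, visits_max=0)
        ctx = NormalizationContext(1.0, 1.0, max_visits={"R1": 0})
        assert acceptance(self._onto(), meta, ctx, CFG) == pytest.approx(0.5)


class TestDetail:
    @pytest.mark.parametrize(
        "d,s,p,expected",
        [
            (1, 2, 7, (1 + 0.5 + 0.7) / 3),
            (0, 0, 0, 0.0),
            (3, 9, 25, 1.0),  # all saturated
        ],
    )
    def test_per_annotation(self, d, s, p, expected):
        cls = OntologyClass(
            id="C:1",
            pref_label="c",
            synonyms=[f"s{i}" for i in range(s)],
            definition_count=d,
            property_count=p,
        )
        a = make_annotation(0, 1, class_id="C:1")
        assert detail_annotation(a, cls, CFG) == pytest.approx(expected)

    def test_worked_example_two_ontologies(self, penicillin):
        anns = annotate(penicillin.document, penicillin.ontologies)
        o1, o2 = penicillin.ontologies
        d1 = detail(o1, select_annotations([a for a in anns if a.ontology_acronym == "O1"], CFG), CFG)
        d2 = detail(o2, select_annotations([a for a in anns if a.ontology_acronym == "O2"], CFG), CFG)
        assert d1 == pytest.approx(0.8667, abs=5e-3)
        assert d2 == pytest.approx(0.125, abs=1e-9)

    def test_empty_selection_gives_zero(self, penicillin):
        sel = select_annotations([], CFG)
        assert detail(penicillin.ontologies[0], sel, CFG) == 0.0


class TestSpecialization:
    def test_worked_example_raw_values(self, penicillin):
        anns = annotate(penicillin.document, penicillin.ontologies)
        o1, o2 = penicillin.ontologies
        raw1 = specialization_raw(o1, [a for a in anns if a.ontology_acronym == "O1"], CFG)
        raw2 = specialization_raw(o2, [a for a in anns if a.ontology_acronym == "O2"], CFG)
        assert raw1 == pytest.approx(31 / math.log10(120_000))
        assert raw2 == pytest.approx(51 / math.log10(800))
        assert round(raw1, 2) == 6.10

    def test_pool_normalization(self, penicillin):
        anns = annotate(penicillin.document, penicillin.ontologies)
        o1, o2 = penicillin.ontologies
        a1 = [a for a in anns if a.ontology_acronym == "O1"]
        a2 = [a for a in anns if a.ontology_acronym == "O2"]
        raw1 = specialization_raw(o1, a1, CFG)
        raw2 = specialization_raw(o2, a2, CFG)
        ctx = NormalizationContext(1.0, max_specialization_raw=max(raw1, raw2))
        assert specialization(o2, a2, ctx, CFG) == pytest.approx(1.0)
        assert specialization(o1, a1, ctx, CFG) == pytest.approx(raw1 / raw2)
        # exactly one candidate attains the maximum (no tie here)
        assert specialization(o1, a1, ctx, CFG) < 1.0

    def test_uses_all_annotations_not_selection(self, blood_cell):
        # six annotations contribute even though only two are selected
        onto = blood_cell.ontologies[0]
        anns = annotate(blood_cell.document, blood_cell.ontologies)
        sel = select_annotations(anns, CFG)
        full = specialization_raw(onto, anns, CFG)
        selected_only = specialization_raw(onto, sel.selected, CFG)
        assert full > selected_only
        assert len(anns) == 6 and len(sel.selected) == 2

    def test_tiny_ontology_size_rejected(self):
        onto = Ontology(acronym="T", classes={"A": OntologyClass(id="A", pref_label="a")})
        with pytest.raises(ConfigurationError):
            specialization_raw(onto, [], CFG)


class TestConfig:
    def test_default_weights_valid(self):
        cfg = RecommenderConfig()
        assert cfg.w_c == 0.55 and cfg.w_a == cfg.w_d == cfg.w_s == 0.15

    def test_bad_weight_sum_rejected(self):
        with pytest.raises(ConfigurationError):
            RecommenderConfig(w_c=0.9, w_a=0.2, w_d=0.15, w_s=0.15)

    def test_bad_set_size_rejected(self):
        with pytest.raises(ConfigurationError):
            RecommenderConfig(max_set_size=1)
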