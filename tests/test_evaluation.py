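"""Location-unit and article-unit metrics, and the error taxonomy."""

import math
import random

import pytest

from scigeo.errors import EvaluationError
from scigeo.evaluation import (
    ERROR_CATEGORIES,
    GroundTruthAnnotation,
    TruthLocation,
    article_unit_scores,
    extraction_precision,
    full_pipeline_precision,
    geocode_is_correct,
    geocoding_accuracy,
    harmonic_f1,
    haversine_km,
    strings_match,
    tally_errors,
)
from scigeo.geocoding import GeocodeResult


def result(record_id=None, lat=0.0, lon=0.0, granularity="locality", name="X"):
    return GeocodeResult(
        query="q", formatted_name=name, granularity=granularity,
        latitude=lat, longitude=lon, record_id=record_id,
    )


class TestExtractionPrecision:
    def test_eighteen_of_nineteen(self):
        strings = [f"s{i}" for i in range(19)]
        judgments = {s: True for s in strings}
        judgments["s0"] = False
        assert round(extraction_precision(strings, judgments), 2) == 0.95

    def test_all_correct(self):
        assert extraction_precision(["a"], {"a": True}) == 1.0

    def test_empty_extraction_not_applicable(self):
        assert extraction_precision([], {}) is None

    def test_missing_judgment_raises(self):
        with pytest.raises(EvaluationError):
            extraction_precision(["a"], {})


class TestGeocodingCorrectness:
    def test_record_id_equality(self):
        truth = TruthLocation("X", record_id="42")
        assert geocode_is_correct(result(record_id="42"), truth)
        assert not geocode_is_correct(result(record_id="43"), truth)

    def test_distance_tolerance_locality(self):
        # ~5 km offset at the equator: within the 25 km locality tolerance
        truth = TruthLocation("X", latitude=0.0, longitude=0.0)
        assert geocode_is_correct(result(lat=0.045, lon=0.0), truth)
        assert not geocode_is_correct(result(lat=0.5, lon=0.0), truth)

    def test_admin_area_wider_tolerance(self):
        truth = TruthLocation("X", latitude=0.0, longitude=0.0)
        near_100km = result(lat=0.9, lon=0.0, granularity="administrative_area")
        assert geocode_is_correct(near_100km, truth)

    def test_no_result_incorrect(self):
        assert not geocode_is_correct(None, TruthLocation("X", record_id="1"))

    def test_accuracy_counts_missing_results_as_wrong(self):
        truth = TruthLocation("X", record_id="1")
        pairs = [(result(record_id="1"), truth), (None, truth)]
        assert geocoding_accuracy(pairs) == 0.5

    def test_haversine_known_quarter_meridian(self):
        # pole to equator along a meridian is a quarter of Earth's circumference
        assert math.isclose(haversine_km(0, 0, 90, 0), math.pi * 6371 / 2, rel_tol=1e-9)


class TestFullPipelinePrecision:
    def test_correct_string_wrong_geocode_is_fp(self):
        truth = TruthLocation("X", record_id="1")
        items = [("X", True, result(record_id="2"), truth)]
        assert full_pipeline_precision(items) == 0.0

    def test_wrong_string_no_geocode_excluded_as_tn(self):
        truth = TruthLocation("X", record_id="1")
        items = [
            ("X", True, result(record_id="1"), truth),
            ("junk", False, None, None),
        ]
        assert full_pipeline_precision(items) == 1.0

    def test_all_correct(self):
        truth = TruthLocation("X", record_id="1")
        items = [("X", True, result(record_id="1"), truth)] * 3
        assert full_pipeline_precision(items) == 1.0

    def test_numerator_bounded_by_tp_count(self):
        rng = random.Random(5)
        truth = TruthLocation("X", record_id="1")
        items = []
        for _ in range(50):
            correct = rng.random() < 0.6
            geocoded = rng.random() < 0.7
            items.append(
                ("X", correct, result(record_id=rng.choice(["1", "2"])) if geocoded else None,
                 truth if correct else None)
            )
        tp_strings = sum(1 for it in items if it[1])
        numerator = sum(
            1 for it in items if it[1] and it[3] and geocode_is_correct(it[2], it[3])
        )
        assert numerator <= tp_strings


class TestHarmonicF1:
    @pytest.mark.parametrize(
        "p,r,expected",
        [
            (0.628, 1.0, 0.771),   # all-mentions baseline, ecology corpus
            (0.408, 1.0, 0.579),   # all-mentions baseline, biomedical corpus
            (0.827, 0.809, 0.818),
            (0.740, 0.769, 0.754),
            (0.0, 0.0, 0.0),
            (1.0, 1.0, 1.0),
        ],
    )
    def test_reference_values(self, p, r, expected):
        assert harmonic_f1(p, r) == pytest.approx(expected, abs=6e-4)

    def test_out_of_range_raises(self):
        with pytest.raises(EvaluationError):
            harmonic_f1(1.2, 0.5)

    def test_bracketed_by_min_max(self):
        rng = random.Random(11)
        for _ in range(200):
            p, r = rng.random(), rng.random()
            if p > 0 and r > 0:
                f1 = harmonic_f1(p, r)
                assert min(p, r) <= f1 <= max(p, r)


class TestArticleUnitScores:
    def _truth(self, aid, strings):
        return GroundTruthAnnotation(
            article_id=aid, truth_locations=[TruthLocation(s) for s in strings]
        )

    def test_perfect_article(self):
        truth = {"a": self._truth("a", ["Nancy", "Lyon"])}
        p, r, f1, _ = article_unit_scores({"a": ["Nancy", "Lyon"]}, truth)
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_mean_over_articles(self):
        truth = {
            "a": self._truth("a", ["Nancy", "Lyon"]),
            "b": self._truth("b", ["Rome"]),
        }
        extracted = {"a": ["Nancy"], "b": ["Rome", "junk"]}
        p, r, _, per_article = article_unit_scores(extracted, truth)
        # per-article (P, R): a=(1, 0.5), b=(0.5, 1) -> corpus means 0.75, 0.75
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(0.75)
        scores = {s.article_id: (s.precision, s.recall) for s in per_article}
        assert scores["a"] == (1.0, 0.5)
        assert scores["b"] == (0.5, 1.0)

    def test_empty_extraction_excluded_from_precision_mean(self):
        truth = {"a": self._truth("a", ["Nancy"]), "b": self._truth("b", ["Rome"])}
        p, r, _, _ = article_unit_scores({"a": ["Nancy"], "b": []}, truth)
        assert p == 1.0  # only article a contributes to the precision mean
        assert r == pytest.approx(0.5)

    def test_empty_truth_excluded_from_recall_mean(self):
        truth = {"a": self._truth("a", ["Nancy"]), "b": self._truth("b", [])}
        p, r, _, _ = article_unit_scores({"a": ["Nancy"], "b": []}, truth)
        assert r == 1.0

    def test_unknown_article_raises(self):
        with pytest.raises(EvaluationError):
            article_unit_scores({"ghost": ["x"]}, {})

    def test_permutation_invariance(self):
        truth = {
            aid: self._truth(aid, [f"Place{aid}"]) for aid in ("a", "b", "c", "d")
        }
        extracted = {"a": ["Placea"], "b": ["junk"], "c": ["Placec", "junk"], "d": []}
        forward = article_unit_scores(extracted, truth)[:3]
        shuffled = article_unit_scores(
            dict(reversed(list(extracted.items()))), dict(reversed(list(truth.items())))
        )[:3]
        assert forward == shuffled

    def test_substring_representation(self):
        assert strings_match("Seville", "Seville, Spain")
        assert strings_match("Seville, Spain", "seville")
        assert not strings_match("Seville", "Granada")


class TestTallyErrors:
    def test_reference_percentages(self):
        failures = (
            [("x", "NER error")] * 12
            + [("x", "text portion not extracted")] * 8
            + [("x", "wrong/no geocode result")] * 9
            + [("x", "comma group")] * 7
            + [("x", "candidate filtering error")] * 3
            + [("x", "non-standard headings")] * 3
            + [("x", "other")] * 2
        )
        tally = tally_errors(failures)
        assert tally["NER error"] == (12, 27.3)
        assert tally["text portion not extracted"] == (8, 18.2)
        assert tally["wrong/no geocode result"] == (9, 20.5)
        assert tally["comma group"] == (7, 15.9)

    def test_empty_failures_all_zero(self):
        tally = tally_errors([])
        assert all(v == (0, 0.0) for v in tally.values())

    def test_unknown_category_raises(self):
        with pytest.raises(EvaluationError):
            tally_errors([("x", "gremlins")])

    def test_percentages_sum_to_hundred(self):
        rng = random.Random(3)
        for _ in range(100):
            failures = [
                ("x", rng.choice(ERROR_CATEGORIES))
                for _ in range(rng.randint(1, 60))
            ]
            total_pct = sum(pct for _, pct in tally_errors(failures).values())
            # each of the 7 categories is rounded to 1 decimal: drift <= 7 * 0.05
            assert abs(total_pct - 100.0) <= 0.35 + 1e-9
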