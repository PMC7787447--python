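"""Evaluation of extraction and geocoding against ground-truth annotations.

Two units of evaluation are supported. At the *location unit*, each extracted
string counts once: extraction precision scores the strings themselves,
geocoding accuracy scores the geocode results of the true-positive strings,
and full-pipeline precision scores the final geocoded output of all extracted
strings (with wrongly extracted strings that return no geocode result counted
as true negatives and excluded from the denominator). At the *article unit*,
precision and recall are scored out of 1 per article and averaged over the
corpus, so multi-site articles are not over-weighted; the two are combined
into F1 by their harmonic mean. An error taxonomy tallies the main source of
each failure.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from scigeo.errors import EvaluationError
from scigeo.location_identification import normalize_text

#: Marker for metrics with an empty denominator (e.g. precision with zero
#: extractions): reported as not-applicable rather than 0.
NOT_APPLICABLE = None

ERROR_CATEGORIES = (
    "NER error",
    "text portion not extracted",
    "wrong/no geocode result",
    "comma group",
    "candidate filtering error",
    "non-standard headings",
    "other",
)

LOCATION_QUALITIES = ("none", "bad", "medium", "good")

#: Geocode-correctness distance tolerances (km) by result granularity, used
#: when the truth provides coordinates but no gazetteer record id.
DISTANCE_TOLERANCE_KM = {
    "point_of_interest": 25.0,
    "locality": 25.0,
    "administrative_area": 200.0,
}


@dataclass
class TruthLocation:
    truth_string: str
    record_id: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None


@dataclass
class GroundTruthAnnotation:
    """Per-article ground truth: the relevant locations and reporting quality."""

    article_id: str
    truth_locations: list[TruthLocation] = field(default_factory=list)
    location_quality: str = "good"

    def __post_init__(self):
        if self.location_quality not in LOCATION_QUALITIES:
            raise EvaluationError(
                f"{self.article_id}: unknown location_quality {self.location_quality!r}"
            )


def load_annotations(path: Union[str, Path]) -> dict[str, GroundTruthAnnotation]:
    """Read a delimited annotation file.

    Tab-separated with header: article_id, truth_string, truth_record_id,
    truth_lat, truth_lon, location_quality. One row per truth location; an
    article with no locations appears as one row with an empty truth_string.
    """
    annotations: dict[str, GroundTruthAnnotation] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            aid = row["article_id"]
            ann = annotations.setdefault(
                aid,
                GroundTruthAnnotation(
                    article_id=aid, location_quality=row.get("location_quality") or "good"
                ),
            )
            if row.get("truth_string"):
                ann.truth_locations.append(
                    TruthLocation(
                        truth_string=row["truth_string"],
                        record_id=row.get("truth_record_id") or None,
                        latitude=float(row["truth_lat"]) if row.get("truth_lat") else None,
                        longitude=float(row["truth_lon"]) if row.get("truth_lon") else None,
                    )
                )
    return annotations


def strings_match(truth_string: str, extracted_string: str) -> bool:
    """Whether an extracted string represents a truth location.

    Case-insensitive on normalized text; equality or containment in either
    direction ('Seville' represents 'Seville, Spain' and vice versa).
    """
    a = normalize_text(truth_string).casefold()
    b = normalize_text(extracted_string).casefold()
    return bool(a) and bool(b) and (a in b or b in a)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres (spherical Earth, R=6371 km)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * 6371.0 * math.asin(math.sqrt(a))


def geocode_is_correct(result, truth: TruthLocation) -> bool:
    """Reproducible surrogate for the manual geocode-correctness judgment.

    Record-id equality when the truth carries a gazetteer id; otherwise a
    great-circle distance tolerance that scales with result granularity
    (25 km for localities and points of interest, 200 km for administrative
    areas), and name equality for country-level results.
    """
    if result is None:
        return False
    if truth.record_id is not None and result.record_id is not None:
        return truth.record_id == result.record_id
    if result.granularity == "country":
        return strings_match(truth.truth_string, result.formatted_name.split(",")[0])
    if truth.latitude is not None and truth.longitude is not None:
        tol = DISTANCE_TOLERANCE_KM.get(result.granularity, 25.0)
        return (
            haversine_km(truth.latitude, truth.longitude, result.latitude, result.longitude)
            <= tol
        )
    return False


def extraction_precision(
    extracted_strings: Sequence[str], judgments: dict[str, bool]
) -> Optional[float]:
    """TP / (TP + FP) over location units.

    ``judgments`` maps each extracted string to True (correct) or False.
    Empty extraction yields the not-applicable marker, never 0.
    """
    if not extracted_strings:
        return NOT_APPLICABLE
    tp = 0
    for s in extracted_strings:
        if s not in judgments:
            raise EvaluationError(f"no judgment for extracted string {s!r}")
        tp += bool(judgments[s])
    return tp / len(extracted_strings)


def geocoding_accuracy(
    tp_geocodes: Sequence[tuple[Optional[object], TruthLocation]]
) -> Optional[float]:
    """Correct geocodes / true-positive strings.

    Input pairs each true-positive string's geocode result (or None) with its
    truth location; a TP with no geocode result counts as incorrect.
    """
    if not tp_geocodes:
        return NOT_APPLICABLE
    correct = sum(geocode_is_correct(res, truth) for res, truth in tp_geocodes)
    return correct / len(tp_geocodes)


def full_pipeline_precision(
    items: Sequence[tuple[str, bool, Optional[object], Optional[TruthLocation]]]
) -> Optional[float]:
    """Precision of the final geocoded output over all extracted strings.

    Each item is (extracted_string, extraction_correct, geocode_result,
    matched_truth). A correct string correctly geocoded is a true positive; a
    wrongly extracted string with no geocode result is a true negative and
    leaves the denominator entirely.
    """
    tp = 0
    denominator = 0
    for _string, correct, result, truth in items:
        if not correct and result is None:
            continue  # true negative
        denominator += 1
        if correct and truth is not None and geocode_is_correct(result, truth):
            tp += 1
    if denominator == 0:
        return NOT_APPLICABLE
    return tp / denominator


def harmonic_f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= p <= 1.0) or not (0.0 <= r <= 1.0):
        raise EvaluationError(f"precision/recall out of [0, 1]: p={p}, r={r}")
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


@dataclass
class ArticleScore:
    article_id: str
    precision: Optional[float]
    recall: Optional[float]


def article_unit_scores(
    extracted_by_article: dict[str, Sequence[str]],
    truth: dict[str, GroundTruthAnnotation],
) -> tuple[Optional[float], Optional[float], Optional[float], list[ArticleScore]]:
    """Article-unit precision, recall, and F1.

    Per article, precision = correct extracted strings / extracted strings
    and recall = truth locations represented by at least one extracted
    string / truth count. Corpus precision and recall are means over
    articles; articles with no extractions are excluded from the precision
    mean, and articles with no truth locations from the recall mean. An
    extracted string is correct when it represents some truth location
    (normalized containment/equality match).
    """
    per_article: list[ArticleScore] = []
    for aid in extracted_by_article:
        if aid not in truth:
            raise EvaluationError(f"article {aid!r} has extractions but no ground truth")
    for aid, ann in sorted(truth.items()):
        extracted = list(extracted_by_article.get(aid, []))
        truths = ann.truth_locations
        if extracted:
            correct = sum(
                any(strings_match(t.truth_string, e) for t in truths) for e in extracted
            )
            precision = correct / len(extracted)
        else:
            precision = NOT_APPLICABLE
        if truths:
            represented = sum(
                any(strings_match(t.truth_string, e) for e in extracted) for t in truths
            )
            recall = represented / len(truths)
        else:
            recall = NOT_APPLICABLE
        per_article.append(ArticleScore(aid, precision, recall))

    precisions = [s.precision for s in per_article if s.precision is not None]
    recalls = [s.recall for s in per_article if s.recall is not None]
    corpus_p = sum(precisions) / len(precisions) if precisions else NOT_APPLICABLE
    corpus_r = sum(recalls) / len(recalls) if recalls else NOT_APPLICABLE
    f1 = (
        harmonic_f1(corpus_p, corpus_r)
        if corpus_p is not None and corpus_r is not None
        else NOT_APPLICABLE
    )
    return corpus_p, corpus_r, f1, per_article


def tally_errors(
    labeled_failures: Sequence[tuple[str, str]]
) -> dict[str, tuple[int, float]]:
    """Count failures per error category, with percentages of the total.

    Each failure is labelled with exactly one category (the main source of
    error). Percentages are rounded to one decimal; an empty failure list
    yields zero counts with zero percentages.
    """
    counts = {cat: 0 for cat in ERROR_CATEGORIES}
    for _aid, category in labeled_failures:
        if category not in counts:
            raise EvaluationError(f"unknown error category {category!r}")
        counts[category] += 1
    total = sum(counts.values())
    return {
        cat: (n, round(100.0 * n / total, 1) if total else 0.0) for cat, n in counts.items()
    }


@dataclass
class EvaluationReport:
    """All corpus-level metrics plus the error-category tallies."""

    extraction_precision: Optional[float]
    geocoding_accuracy: Optional[float]
    full_pipeline_precision: Optional[float]
    article_unit_precision: Optional[float]
    article_unit_recall: Optional[float]
    article_unit_f1: Optional[float]
    per_article: list[ArticleScore] = field(default_factory=list)
    error_counts: dict[str, tuple[int, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        rounded = lambda v: None if v is None else round(v, 3)
        return {
            "extraction_precision": rounded(self.extraction_precision),
            "geocoding_accuracy": rounded(self.geocoding_accuracy),
            "full_pipeline_precision": rounded(self.full_pipeline_precision),
            "article_unit_precision": rounded(self.article_unit_precision),
            "article_unit_recall": rounded(self.article_unit_recall),
            "article_unit_f1": rounded(self.article_unit_f1),
            "per_article": [
                {"article_id": s.article_id, "precision": rounded(s.precision),
                 "recall": rounded(s.recall)}
                for s in self.per_article
            ],
            "error_counts": {
                cat: {"count": n, "percent": pct} for cat, (n, pct) in self.error_counts.items()
            },
        }

    def as_text(self) -> str:
        fmt = lambda v: "n/a" if v is None else f"{v:.3f}"
        lines = [
            "location unit:",
            f"  extraction precision    {fmt(self.extraction_precision)}",
            f"  geocoding accuracy      {fmt(self.geocoding_accuracy)}",
            f"  full pipeline precision {fmt(self.full_pipeline_precision)}",
            "article unit:",
            f"  precision {fmt(self.article_unit_precision)}"
            f"  recall {fmt(self.article_unit_recall)}"
            f"  F1 {fmt(self.article_unit_f1)}",
        ]
        if self.error_counts:
            lines.append("errors:")
            for cat, (n, pct) in self.error_counts.items():
                lines.append(f"  {cat:28s} {n:4d} {pct:5.1f}%")
        return "\n".join(lines)
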