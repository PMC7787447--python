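"""Spatial (GeoJSON) and tabular output of extraction results.

Every geocoded extraction record becomes one point feature in a GeoJSON
FeatureCollection, ready to drop onto any web map; when an evaluation report
is available, each feature carries a TP/FP correctness label so the map shows
full-pipeline precision at a glance. A flat CSV writer provides the tabular
companion output.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence, Union

from scigeo.evaluation import GroundTruthAnnotation, geocode_is_correct, strings_match
from scigeo.pipeline_orchestration import ExtractionRecord

RECORD_COLUMNS = (
    "article_id",
    "location_string",
    "heading",
    "sentence_text",
    "formatted_name",
    "granularity",
    "latitude",
    "longitude",
    "record_id",
    "stage_flags",
)


def _correctness_label(
    rec: ExtractionRecord, truth: dict[str, GroundTruthAnnotation]
) -> Optional[str]:
    ann = truth.get(rec.article_id)
    if ann is None:
        return None
    for t in ann.truth_locations:
        if strings_match(t.truth_string, rec.location_string):
            return "TP" if geocode_is_correct(rec.geocode, t) else "FP"
    return "FP"


def build_geojson(
    records: Sequence[ExtractionRecord],
    truth: Optional[dict[str, GroundTruthAnnotation]] = None,
) -> tuple[dict, int]:
    """Build a GeoJSON FeatureCollection from geocoded records.

    Returns (feature_collection, skipped_count): one point feature per record
    with a geocode result (coordinates ordered longitude, latitude per the
    GeoJSON convention); ungeocoded records are skipped and counted. When
    ground truth is supplied each feature carries a TP/FP label.
    """
    features = []
    skipped = 0
    for rec in records:
        if rec.geocode is None:
            skipped += 1
            continue
        properties = {
            "article_id": rec.article_id,
            "location_string": rec.location_string,
            "formatted_name": rec.geocode.formatted_name,
            "granularity": rec.geocode.granularity,
        }
        if truth is not None:
            label = _correctness_label(rec, truth)
            if label is not None:
                properties["correctness"] = label
        feature = {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [rec.geocode.longitude, rec.geocode.latitude],
            },
            "properties": properties,
        }
        if rec.geocode.bounding_box is not None:
            feature["properties"]["bounding_box"] = list(rec.geocode.bounding_box)
        features.append(feature)
    return {"type": "FeatureCollection", "features": features}, skipped


def write_geojson(
    records: Sequence[ExtractionRecord],
    path: Union[str, Path],
    truth: Optional[dict[str, GroundTruthAnnotation]] = None,
) -> int:
    """Write the FeatureCollection to ``path``; returns the skipped count."""
    collection, skipped = build_geojson(records, truth)
    Path(path).write_text(
        json.dumps(collection, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return skipped


def write_records_table(records: Sequence[ExtractionRecord], path: Union[str, Path]) -> None:
    """Write records as CSV with a fixed, documented column order.

    Sentence text is quoted by the csv module, so embedded commas and quotes
    round-trip safely.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for rec in records:
            geo = rec.geocode
            writer.writerow(
                [
                    rec.article_id,
                    rec.location_string,
                    rec.heading or "",
                    rec.sentence_text,
                    geo.formatted_name if geo else "",
                    geo.granularity if geo else "",
                    geo.latitude if geo else "",
                    geo.longitude if geo else "",
                    (geo.record_id or "") if geo else "",
                    rec.stage_flags,
                ]
            )
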