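"""Convert cleaned location strings to structured spatial representations.

Geocoding backends are pluggable: a backend takes a query string and returns
an ordered result list, each result carrying a fully qualified name, a
granularity label, and coordinates. The bundled default is a deterministic
offline gazetteer backend over a GeoNames-dump-style TSV, so the whole
pipeline runs reproducibly with no network access. Remote HTTP services can
be wrapped behind the same contract.

Disambiguation in the offline backend follows a fixed ranking: exact
primary-name match beats exact alternate-name match beats all-query-tokens
containment; within a match class the most populous record wins (the
population heuristic common in toponym-resolution work), with the record id
as the final deterministic tie-break. Qualified queries ('Paris, Texas') are
resolved by matching the head name and requiring each qualifier to appear in
the record's administrative containment path or country.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union

from scigeo.errors import BackendError, GazetteerLoadError
from scigeo.location_identification import normalize_text

logger = logging.getLogger(__name__)

GRANULARITIES = ("point_of_interest", "locality", "administrative_area", "country")

#: GeoNames-style single-letter feature classes mapped to granularity labels.
_FEATURE_CLASS_MAP = {
    "P": "locality",
    "A": "administrative_area",
    "S": "point_of_interest",
    "C": "country",
}


@dataclass(frozen=True)
class GazetteerRecord:
    record_id: str
    primary_name: str
    alternate_names: frozenset[str]
    feature_class: str
    latitude: float
    longitude: float
    population: int
    country_code: str
    admin_path: tuple[str, ...]  # ordered containment, e.g. ("CA", "USA")

    @property
    def granularity(self) -> str:
        return _FEATURE_CLASS_MAP.get(self.feature_class, self.feature_class)

    @property
    def formatted_name(self) -> str:
        return ", ".join((self.primary_name,) + self.admin_path)


@dataclass
class GeocodeResult:
    """Structured, spatial representation of one geocoded query."""

    query: str
    formatted_name: str
    granularity: str
    latitude: float
    longitude: float
    bounding_box: Optional[tuple[float, float, float, float]] = None
    record_id: Optional[str] = None
    backend_id: str = ""

    def __post_init__(self):
        if not self.formatted_name:
            raise ValueError("formatted_name must be non-empty")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} out of bounds")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} out of bounds")


class Gazetteer:
    """In-memory gazetteer with a normalized name index."""

    def __init__(self, records: Sequence[GazetteerRecord]):
        self.records = list(records)
        self._by_primary: dict[str, list[GazetteerRecord]] = {}
        self._by_alternate: dict[str, list[GazetteerRecord]] = {}
        for rec in self.records:
            self._by_primary.setdefault(_norm(rec.primary_name), []).append(rec)
            for alt in rec.alternate_names:
                self._by_alternate.setdefault(_norm(alt), []).append(rec)

    def __len__(self) -> int:
        return len(self.records)


def _norm(name: str) -> str:
    return normalize_text(name).casefold()


def load_gazetteer(path: Union[str, Path]) -> Gazetteer:
    """Load a tab-separated gazetteer file.

    Columns: id, name, alternate names (pipe-separated), feature class,
    latitude, longitude, population, country code, admin path
    (pipe-separated). Malformed rows are skipped with a warning naming the
    line number; a file yielding zero valid records is an error.
    """
    records: list[GazetteerRecord] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9:
            logger.warning("%s line %d: expected 9 columns, got %d — skipped", path, lineno, len(cols))
            continue
        try:
            lat, lon = float(cols[4]), float(cols[5])
            population = int(cols[6] or 0)
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise ValueError(f"coordinates out of bounds ({lat}, {lon})")
            if population < 0:
                raise ValueError("negative population")
            records.append(
                GazetteerRecord(
                    record_id=cols[0],
                    primary_name=cols[1],
                    alternate_names=frozenset(a for a in cols[2].split("|") if a),
                    feature_class=cols[3],
                    latitude=lat,
                    longitude=lon,
                    population=population,
                    country_code=cols[7],
                    admin_path=tuple(a for a in cols[8].split("|") if a),
                )
            )
        except ValueError as exc:
            logger.warning("%s line %d: %s — skipped", path, lineno, exc)
    if not records:
        raise GazetteerLoadError(f"{path}: no valid gazetteer rows")
    logger.info("loaded %d gazetteer records from %s", len(records), path)
    return Gazetteer(records)


# match classes, best first
_EXACT_PRIMARY, _EXACT_ALTERNATE, _TOKENS_CONTAINED = 0, 1, 2


def _qualifiers_satisfied(rec: GazetteerRecord, qualifiers: Sequence[str]) -> bool:
    haystack = {_norm(a) for a in rec.admin_path}
    haystack.add(_norm(rec.country_code))
    for q in qualifiers:
        if _norm(q) not in haystack:
            return False
    return True


def gazetteer_lookup(query: str, gazetteer: Gazetteer) -> list[GazetteerRecord]:
    """Rank gazetteer records for a query.

    Qualified queries ('X, Y[, Z]') match X as the name and require every
    qualifier to appear in the record's admin path or country code. Ranking:
    match class (exact primary > exact alternate > all-query-tokens
    contained in the primary name), then population descending, then
    record id ascending.
    """
    parts = [p.strip() for p in query.split(",") if p.strip()]
    if not parts:
        return []
    head, qualifiers = parts[0], parts[1:]
    head_norm = _norm(head)

    scored: dict[str, tuple[int, GazetteerRecord]] = {}

    def consider(rec: GazetteerRecord, match_class: int) -> None:
        if qualifiers and not _qualifiers_satisfied(rec, qualifiers):
            return
        existing = scored.get(rec.record_id)
        if existing is None or match_class < existing[0]:
            scored[rec.record_id] = (match_class, rec)

    for rec in gazetteer._by_primary.get(head_norm, []):
        consider(rec, _EXACT_PRIMARY)
    for rec in gazetteer._by_alternate.get(head_norm, []):
        consider(rec, _EXACT_ALTERNATE)
    head_tokens = set(head_norm.split())
    if head_tokens:
        for rec in gazetteer.records:
            if head_tokens <= set(_norm(rec.primary_name).split()):
                consider(rec, _TOKENS_CONTAINED)

    ranked = sorted(
        scored.values(), key=lambda mr: (mr[0], -mr[1].population, mr[1].record_id)
    )
    return [rec for _, rec in ranked]


class GeocodingBackend(Protocol):
    """Contract for geocoding backends: ordered results for a query."""

    backend_id: str

    def lookup(self, query: str) -> list[GeocodeResult]: ...


class GazetteerBackend:
    """Offline, deterministic backend over a loaded gazetteer."""

    def __init__(self, gazetteer: Gazetteer, backend_id: str = "gazetteer"):
        self.gazetteer = gazetteer
        self.backend_id = backend_id

    def lookup(self, query: str) -> list[GeocodeResult]:
        results = []
        for rec in gazetteer_lookup(query, self.gazetteer):
            results.append(
                GeocodeResult(
                    query=query,
                    formatted_name=rec.formatted_name,
                    granularity=rec.granularity,
                    latitude=rec.latitude,
                    longitude=rec.longitude,
                    record_id=rec.record_id,
                    backend_id=self.backend_id,
                )
            )
        return results


class Geocoder:
    """Backend wrapper adding per-run caching and a retry policy.

    Results are cached per (backend, query) so repeated strings across a
    corpus cost one lookup. Transport failures are retried; persistent
    failure raises a BackendError rather than silently returning no result.
    """

    def __init__(self, backend: GeocodingBackend, max_retries: int = 2):
        self.backend = backend
        self.max_retries = max_retries
        self._cache: dict[tuple[str, str], Optional[GeocodeResult]] = {}

    def geocode(self, query: str) -> Optional[GeocodeResult]:
        """Return the top-ranked result for a cleaned query, or None."""
        if not query or not query.strip():
            return None
        key = (self.backend.backend_id, query)
        if key in self._cache:
            return self._cache[key]
        last_exc: Optional[Exception] = None
        for _ in range(self.max_retries + 1):
            try:
                results = self.backend.lookup(query)
                top = results[0] if results else None
                self._cache[key] = top
                return top
            except Exception as exc:  # noqa: BLE001 — backend transport failure
                last_exc = exc
        raise BackendError(query, str(last_exc))
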