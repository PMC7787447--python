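"""Target the article portions likely to contain relevant locations.

A :class:`DomainProfile` bundles every piece of per-corpus configuration:
heading patterns for methods/study-site/patient sections, lexicons used when
assembling and filtering candidates, and whether the article title is worth
mining. Two built-in profiles ship with the package — ``orchards`` (ecology
field studies, where titles and study-site sections carry locations) and
``cancer`` (biomedical studies, where patient/sample sections name hospitals
and cities) — and every list is user-overridable from a YAML file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from scigeo.corpus_io import (
    DEFAULT_REFERENCES_PATTERNS,
    ArticleDocument,
    matches_references_heading,
    paragraph_beginning,
)
from scigeo.errors import ScigeoError

logger = logging.getLogger(__name__)

US_STATE_ABBREVIATIONS = frozenset(
    """AL AK AZ AR CA CO CT DE FL GA HI ID IL IN IA KS KY LA ME MD MA MI MN MS
    MO MT NE NV NH NJ NM NY NC ND OH OK OR PA RI SC SD TN TX UT VT VA WA WV WI
    WY DC""".split()
)

CARDINAL_DIRECTION_WORDS = frozenset(
    {
        "north", "south", "east", "west",
        "northern", "southern", "eastern", "western",
        "northeastern", "northwestern", "southeastern", "southwestern",
        "central",
    }
)

GEOGRAPHIC_FEATURE_WORDS = frozenset(
    {"region", "county", "park", "valley", "river", "province", "district", "island"}
)

DEFAULT_CONNECTOR_WORDS = frozenset({"in", "upon", "of", "at", "near", "the"})

DEFAULT_KEEP_WORDS = frozenset(
    {"University", "Institute", "Hospital", "Medical School", "Centre", "Center", "Clinic"}
)

DEFAULT_DISCARD_WORDS = frozenset(
    {"Inc", "Inc.", "Ltd", "Ltd.", "GmbH", "Corp", "Corp.", "Co.", "LLC", "S.A.", "AG", "KGaA"}
)


@dataclass
class DomainProfile:
    """All corpus-specific pipeline configuration.

    ``heading_patterns`` is an ordered list of case-insensitive regular
    expressions matched with word boundaries against section headings and
    plain-text paragraph beginnings. ``candidate_extension_lexicon`` holds
    words (cardinal directions, geographic feature types) absorbed into
    candidate strings adjacent to entities; ``keep_words`` / ``discard_words``
    drive the filtering stage; ``connector_words`` bridge entity tokens within
    a candidate.
    """

    profile_id: str
    heading_patterns: list[str]
    use_title: bool = False
    candidate_extension_lexicon: frozenset[str] = frozenset()
    keep_words: frozenset[str] = DEFAULT_KEEP_WORDS
    discard_words: frozenset[str] = DEFAULT_DISCARD_WORDS
    connector_words: frozenset[str] = DEFAULT_CONNECTOR_WORDS
    state_abbreviations: frozenset[str] = US_STATE_ABBREVIATIONS
    references_patterns: tuple[str, ...] = DEFAULT_REFERENCES_PATTERNS

    def __post_init__(self):
        if not self.heading_patterns:
            raise ScigeoError(f"profile {self.profile_id!r}: heading_patterns must be non-empty")
        self.candidate_extension_lexicon = frozenset(
            w.lower() for w in self.candidate_extension_lexicon
        )
        self.connector_words = frozenset(w.lower() for w in self.connector_words)
        overlap = {k.lower() for k in self.keep_words} & {d.lower() for d in self.discard_words}
        if overlap:
            raise ScigeoError(f"profile {self.profile_id!r}: keep/discard overlap: {overlap}")
        self._compiled = [
            re.compile(rf"\b(?:{pat})\b", flags=re.IGNORECASE) for pat in self.heading_patterns
        ]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "DomainProfile":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key in ("candidate_extension_lexicon", "keep_words", "discard_words",
                    "connector_words", "state_abbreviations"):
            if key in data:
                data[key] = frozenset(data[key])
        if "references_patterns" in data:
            data["references_patterns"] = tuple(data["references_patterns"])
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {
            "profile_id": self.profile_id,
            "heading_patterns": list(self.heading_patterns),
            "use_title": self.use_title,
            "candidate_extension_lexicon": sorted(self.candidate_extension_lexicon),
            "keep_words": sorted(self.keep_words),
            "discard_words": sorted(self.discard_words),
            "connector_words": sorted(self.connector_words),
            "state_abbreviations": sorted(self.state_abbreviations),
            "references_patterns": list(self.references_patterns),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def orchards_profile() -> DomainProfile:
    """Built-in profile for ecology field-study corpora.

    Relevant headings feature words like 'region', 'area', and 'site'; titles
    often name the study region, and location strings frequently include
    cardinal-direction and feature-type words.
    """
    return DomainProfile(
        profile_id="orchards",
        heading_patterns=[
            r"materials?\s+and\s+methods?",
            r"methods?",
            r"study\s+sites?",
            r"study\s+area",
            r"site\s+description",
            r"region",
            r"area",
            r"site",
            r"sampling",
            r"field",
        ],
        use_title=True,
        candidate_extension_lexicon=CARDINAL_DIRECTION_WORDS | GEOGRAPHIC_FEATURE_WORDS,
    )


def cancer_profile() -> DomainProfile:
    """Built-in profile for biomedical corpora (patient/sample provenance)."""
    return DomainProfile(
        profile_id="cancer",
        heading_patterns=[
            r"materials?\s+and\s+methods?",
            r"methods?",
            r"patients?",
            r"samples?",
            r"specimens?",
            r"subjects?",
            r"tumou?r\s+material",
            r"cases?",
        ],
        use_title=False,
        candidate_extension_lexicon=frozenset(),
    )


BUILTIN_PROFILES = {"orchards": orchards_profile, "cancer": cancer_profile}


def get_profile(name_or_path: str) -> DomainProfile:
    """Resolve a built-in profile name or a YAML profile file path."""
    if name_or_path in BUILTIN_PROFILES:
        return BUILTIN_PROFILES[name_or_path]()
    return DomainProfile.from_yaml(name_or_path)


def match_heading(heading: Optional[str], profile: DomainProfile) -> Optional[int]:
    """Match a heading against the profile's patterns.

    Returns the index of the first matching pattern, or None. Matching is
    substring-with-word-boundary so numbered headings like
    '2.1 Study site description' match. References headings never match.
    """
    if not heading or not heading.strip():
        return None
    if matches_references_heading(heading, profile.references_patterns):
        return None
    for i, pat in enumerate(profile._compiled):
        if pat.search(heading):
            return i
    return None


@dataclass
class TargetedText:
    """The article portions selected for location identification."""

    source_used: str  # "structured_xml" | "plain_text"
    targets: list[tuple[Optional[str], list[str]]] = field(default_factory=list)
    title: Optional[str] = None


#: Cap on the number of paragraphs a plain-text heading match may claim.
PLAIN_TEXT_SPAN_CAP = 10

_NUMBERED_HEADING = re.compile(r"^\s*\d+(\.\d+)*\.?\s+\S")


def _looks_like_heading(paragraph: str) -> bool:
    """Heuristic heading detector for plain text: all-caps, numbered, or a
    single short line with no terminal period."""
    first_line = paragraph.split("\n", 1)[0].strip()
    if not first_line:
        return False
    if first_line.isupper():
        return True
    if _NUMBERED_HEADING.match(first_line):
        return True
    single_line = "\n" not in paragraph.strip()
    return single_line and len(first_line) <= 60 and not first_line.endswith(".")


def extract_target_text(
    xml_doc: Optional[ArticleDocument],
    text_doc: Optional[ArticleDocument],
    profile: DomainProfile,
) -> TargetedText:
    """Select relevant article portions, preferring the XML representation.

    Headings are matched in the XML section tree and against plain-text
    paragraph beginnings. When the XML representation yields at least one
    match, it is used exclusively; the plain-text representation is a fallback
    for articles whose XML conversion exposed no usable headings. The title is
    taken from the XML document when the profile mines titles.
    """
    if xml_doc is None and text_doc is None:
        raise ScigeoError("extract_target_text requires at least one document representation")

    title = None
    if profile.use_title:
        for doc in (xml_doc, text_doc):
            if doc is not None and doc.title:
                title = doc.title
                break

    xml_targets: list[tuple[Optional[str], list[str]]] = []
    if xml_doc is not None:
        for sec in xml_doc.sections:
            if sec.is_references:
                continue
            if match_heading(sec.heading, profile) is not None and sec.paragraphs:
                xml_targets.append((sec.heading, list(sec.paragraphs)))
    if xml_targets:
        return TargetedText(source_used="structured_xml", targets=xml_targets, title=title)

    text_targets: list[tuple[Optional[str], list[str]]] = []
    if text_doc is not None:
        paragraphs: list[str] = []
        for sec in text_doc.sections:
            if not sec.is_references:
                paragraphs.extend(sec.paragraphs)
        i = 0
        while i < len(paragraphs):
            beginning = paragraph_beginning(paragraphs[i])
            if match_heading(beginning, profile) is not None and _looks_like_heading(paragraphs[i]):
                span: list[str] = []
                j = i + 1
                while (
                    j < len(paragraphs)
                    and len(span) < PLAIN_TEXT_SPAN_CAP
                    and not _looks_like_heading(paragraphs[j])
                ):
                    span.append(paragraphs[j])
                    j += 1
                body = paragraphs[i].split("\n", 1)
                if len(body) > 1 and body[1].strip():
                    span.insert(0, body[1].strip())
                text_targets.append((beginning.strip(), span))
                i = j
            else:
                i += 1
    if text_targets:
        return TargetedText(source_used="plain_text", targets=text_targets, title=title)

    logger.warning("no relevant headings matched in either representation")
    return TargetedText(
        source_used="structured_xml" if xml_doc is not None else "plain_text",
        targets=[],
        title=title,
    )


def whole_article_text(doc: ArticleDocument) -> list[tuple[Optional[str], str]]:
    """All (heading, paragraph) pairs of the article, excluding references.

    Used when section targeting is disabled and the whole article is
    processed.
    """
    out: list[tuple[Optional[str], str]] = []
    for sec in doc.sections:
        if sec.is_references:
            continue
        for para in sec.paragraphs:
            out.append((sec.heading, para))
    return out
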