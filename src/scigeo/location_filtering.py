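"""Filter location candidates down to relevant content locations.

The identification stage favours recall; this stage restores precision by
rejecting candidates that are not relevant locations: strings with no
location-tagged token, suspected company addresses (discard words such as
'Inc' or 'GmbH'), and citation patterns. Candidates containing a keep word
('University', 'Institute', 'Hospital', ...) always survive — institutions
are the archetypal relevant locations in biomedical corpora even when the
tagger labels them organizations. Retained strings are then cleaned of
trailing prepositions and punctuation, and deduplicated per article before
geocoding.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from scigeo.location_identification import (
    LOCATION,
    PERSON,
    LocationCandidate,
    Sentence,
    join_tokens,
)
from scigeo.section_targeting import DomainProfile

logger = logging.getLogger(__name__)

REJECTION_REASONS = (
    "no_location_tag",
    "discard_word",
    "tag_word_combination",
    "empty_after_clean",
)

FILTER_MODES = ("full", "locations_only", "no_filter")


@dataclass
class ContentLocation:
    """A candidate after filtering, with its rejection status."""

    location_string: str
    sentence: Sentence
    article_id: str
    rejected: bool = False
    rejection_reason: Optional[str] = None
    duplicate_count: int = 0

    def __post_init__(self):
        if not self.rejected and self.rejection_reason is not None:
            raise ValueError("unrejected location must not carry a rejection reason")


_YEAR_RE = re.compile(r"^(1[5-9]\d{2}|20\d{2})$")


def _rule_person_year(candidate: LocationCandidate) -> bool:
    """Citation pattern: a PERSON-tagged token immediately before a year-like
    token (within the span or just after it) — 'Smith 1998'."""
    sent_tokens = candidate.sentence.tokens
    start, end = candidate.span
    for i in range(start, end):
        if sent_tokens[i].ner_tag == PERSON and i + 1 < len(sent_tokens):
            if _YEAR_RE.match(sent_tokens[i + 1].surface):
                return True
    return False


def _rule_org_parenthetical_product(candidate: LocationCandidate) -> bool:
    """Company pattern: an all-ORGANIZATION span inside parentheses
    immediately following a product-like capitalized token."""
    if any(t == LOCATION for t in candidate.tag_sequence):
        return False
    if not all(t == "ORGANIZATION" for t in candidate.tag_sequence if t != "OTHER"):
        return False
    sent_tokens = candidate.sentence.tokens
    start = candidate.span[0]
    if start >= 2 and sent_tokens[start - 1].surface == "(":
        prev = sent_tokens[start - 2]
        if prev.pos_tag == "NNP" and prev.ner_tag == "OTHER":
            return True
    return False


#: Token (tag, word) combination rules: each returns True when the candidate
#: should be rejected as a citation/company artifact. User-extensible.
DEFAULT_TAG_WORD_RULES: tuple[Callable[[LocationCandidate], bool], ...] = (
    _rule_person_year,
    _rule_org_parenthetical_product,
)


def _contains_word(text: str, word: str) -> bool:
    return re.search(rf"(?<!\w){re.escape(word)}(?!\w)", text, flags=re.IGNORECASE) is not None


def _truncate_to_locations(candidate: LocationCandidate) -> Optional[str]:
    """For locations-only mode: keep the sub-span from the first to the last
    LOCATION-tagged token (intervening bridge words included)."""
    start, end = candidate.span
    tokens = candidate.sentence.tokens
    loc_idx = [i for i in range(start, end) if tokens[i].ner_tag == LOCATION]
    if not loc_idx:
        return None
    return join_tokens([tokens[i].surface for i in range(loc_idx[0], loc_idx[-1] + 1)])


def filter_candidates(
    candidates: Sequence[LocationCandidate],
    profile: DomainProfile,
    mode: str = "full",
    tag_word_rules: Sequence[Callable[[LocationCandidate], bool]] = DEFAULT_TAG_WORD_RULES,
) -> list[ContentLocation]:
    """Apply the relevance filter to assembled candidates.

    Modes
    -----
    ``full``
        (1) keep-word override: candidates containing a keep word survive the
        later rules; (2) discard-word rejection; (3) rejection of spans with
        no LOCATION-tagged token; (4) token (tag, word) combination rules
        (citation/company patterns).
    ``locations_only``
        Only spans with a LOCATION-tagged token are kept, truncated to their
        location-tagged tokens (plus bridges). Simplified variant used to
        measure the value of resolving person/organization tags.
    ``no_filter``
        Every candidate passes through unrejected (ablation).

    Every rejection carries its reason for the reject log.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}")
    out: list[ContentLocation] = []
    for cand in candidates:
        article_id = cand.sentence.article_id
        if mode == "no_filter":
            out.append(ContentLocation(cand.candidate_string, cand.sentence, article_id))
            continue
        if mode == "locations_only":
            truncated = _truncate_to_locations(cand)
            if truncated is None:
                out.append(
                    ContentLocation(
                        cand.candidate_string, cand.sentence, article_id,
                        rejected=True, rejection_reason="no_location_tag",
                    )
                )
            else:
                out.append(ContentLocation(truncated, cand.sentence, article_id))
            continue
        # mode == "full"
        has_keep = any(_contains_word(cand.candidate_string, kw) for kw in profile.keep_words)
        reason: Optional[str] = None
        if not has_keep:
            if any(_contains_word(cand.candidate_string, dw) for dw in profile.discard_words):
                reason = "discard_word"
            elif LOCATION not in cand.tag_sequence:
                reason = "no_location_tag"
            elif any(rule(cand) for rule in tag_word_rules):
                reason = "tag_word_combination"
        out.append(
            ContentLocation(
                cand.candidate_string, cand.sentence, article_id,
                rejected=reason is not None, rejection_reason=reason,
            )
        )
    return out


_TRAILING_PUNCT = {",", ".", ";", ":"}


def clean_location_string(s: str, connector_words: frozenset[str] = frozenset({"in", "upon", "of", "at", "near", "the"})) -> str:
    """Strip trailing prepositions/punctuation and dangling parentheses.

    Applied iteratively until a fixed point; balanced parentheses are
    preserved. Idempotent and never lengthens its input.
    """
    prev = None
    while s != prev:
        prev = s
        s = s.strip()
        while s and s[-1] in _TRAILING_PUNCT:
            s = s[:-1].rstrip()
        words = s.split()
        if words and words[-1].lower() in connector_words:
            s = " ".join(words[:-1])
        # dangling parens at either edge
        if s.startswith(")"):
            s = s[1:].lstrip()
        if s.endswith("(") :
            s = s[:-1].rstrip()
        if s.count("(") > s.count(")") and s.startswith("("):
            s = s[1:].lstrip()
        if s.count(")") > s.count("(") and s.endswith(")"):
            s = s[:-1].rstrip()
    return s


def clean_locations(
    locations: Sequence[ContentLocation], profile: DomainProfile
) -> list[ContentLocation]:
    """Clean the string of every kept location; empty results are flagged."""
    out: list[ContentLocation] = []
    for loc in locations:
        if loc.rejected:
            out.append(loc)
            continue
        cleaned = clean_location_string(loc.location_string, profile.connector_words)
        if not cleaned:
            out.append(
                ContentLocation(
                    loc.location_string, loc.sentence, loc.article_id,
                    rejected=True, rejection_reason="empty_after_clean",
                )
            )
        else:
            out.append(ContentLocation(cleaned, loc.sentence, loc.article_id))
    return out


def split_comma_separated_countries(
    locations: Sequence[ContentLocation], country_names: frozenset[str]
) -> list[ContentLocation]:
    """Split candidates that are comma-separated sequences of country names.

    Multi-country studies sometimes list their countries in one sentence
    ("... in France, Spain, Italy"), which candidate assembly keeps as one
    comma group. When every comma-separated part of a kept location is a
    known country name (and there are at least two), the location is split
    into one record per country. Off by default: comma groups are otherwise
    kept whole, since splitting qualified strings like "Paris, France" would
    destroy geocoding context.
    """
    known = {n.casefold() for n in country_names}
    out: list[ContentLocation] = []
    for loc in locations:
        parts = [p.strip() for p in loc.location_string.split(",")]
        if (
            not loc.rejected
            and len(parts) >= 2
            and all(p.casefold() in known for p in parts)
        ):
            for part in parts:
                out.append(ContentLocation(part, loc.sentence, loc.article_id))
        else:
            out.append(loc)
    return out


def deduplicate_locations(locations: Sequence[ContentLocation]) -> list[ContentLocation]:
    """Case-insensitive deduplication of kept locations within one article.

    The first occurrence (document order) is kept and records how many
    duplicates were dropped. Rejected locations pass through untouched.
    """
    seen: dict[str, ContentLocation] = {}
    out: list[ContentLocation] = []
    for loc in locations:
        if loc.rejected:
            out.append(loc)
            continue
        key = loc.location_string.casefold()
        if key in seen:
            seen[key].duplicate_count += 1
        else:
            seen[key] = loc
            out.append(loc)
    for key, loc in seen.items():
        if loc.duplicate_count:
            logger.debug("deduplicated %r: %d duplicates", loc.location_string, loc.duplicate_count)
    return out
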