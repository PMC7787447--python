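"""Normalize, segment, tag, and chunk targeted text into location candidates.

This is the high-recall stage: any token sequence containing at least one
named entity is retained as a candidate, with entity tokens bridged across
connector words ('in', 'upon', ...), commas, parentheses, two-letter state
abbreviations, and — per domain profile — cardinal-direction and
geographic-feature words. Keeping qualified strings together ('Nancy (East of
France)' rather than 'Nancy' and 'France') gives the geocoding stage better
context. Relevance judgments are deferred to the filtering stage.

The entity tagger is an injectable contract (one tag per token from
{LOCATION, PERSON, ORGANIZATION, OTHER}, deterministic). The package ships a
lexicon-based tagger driven by a phrase->tag TSV, which doubles as the
deterministic mock for tests; adapters for pretrained 3-class NER models can
implement the same contract.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union

from scigeo.errors import StageError
from scigeo.section_targeting import DomainProfile

LOCATION = "LOCATION"
PERSON = "PERSON"
ORGANIZATION = "ORGANIZATION"
OTHER = "OTHER"
NER_TAGS = (LOCATION, PERSON, ORGANIZATION, OTHER)

#: Gap-bridging limit: at most this many consecutive non-entity tokens may be
#: absorbed between two entity tokens. Prevents whole-sentence candidates in
#: entity-dense sentences.
MAX_BRIDGE_GAP = 3

#: Cap on untagged edge words absorbed on either side of a span ('northern
#: France', 'Madison, WI'). Bounding the edges keeps maximal spans disjoint.
MAX_EDGE_RUN = 2

#: Sentence boundaries are suppressed inside parentheticals shorter than this,
#: so coordinate groups like "(43.77 N, 11.26 E)" stay within one sentence.
PARENTHETICAL_NO_SPLIT_CHARS = 60


def normalize_text(s: str) -> str:
    """Canonicalize text: strip diacritics, collapse exotic whitespace.

    Compatibility-decomposes the string, removes combining marks (so 'Zürich'
    becomes 'Zurich'), and collapses any whitespace run to a single space.
    Idempotent.
    """
    decomposed = unicodedata.normalize("NFKD", s)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return re.sub(r"\s+", " ", stripped).strip()


@dataclass
class Token:
    surface: str
    normalized: str
    pos_tag: str
    ner_tag: str = OTHER

    def __post_init__(self):
        if self.ner_tag not in NER_TAGS:
            raise ValueError(f"invalid ner_tag {self.ner_tag!r}")


@dataclass
class Sentence:
    """A tagged sentence with full provenance back to its article."""

    tokens: list[Token]
    raw_text: str
    article_id: str = ""
    heading: Optional[str] = None
    paragraph_index: int = 0
    sentence_index: int = 0

    @property
    def provenance(self) -> tuple:
        return (self.article_id, self.heading, self.paragraph_index, self.sentence_index)


@dataclass
class LocationCandidate:
    """A token span hypothesized to describe a location."""

    span: tuple[int, int]  # [start, end) token indices within the sentence
    candidate_string: str
    tag_sequence: list[str]
    sentence: Sentence

    @property
    def tokens(self) -> list[Token]:
        return self.sentence.tokens[self.span[0]:self.span[1]]


class EntityTagger(Protocol):
    """Contract for pluggable entity taggers.

    Maps an ordered token-surface sequence to one tag per token from
    {LOCATION, PERSON, ORGANIZATION, OTHER}. Must be pure: identical input
    yields identical output.
    """

    def tag(self, surfaces: Sequence[str]) -> list[str]: ...


class LexiconTagger:
    """Deterministic tagger backed by a phrase -> tag lexicon.

    Phrases may span multiple tokens; longest match wins, ties broken by the
    leftmost start. Matching is case-sensitive on normalized surfaces, which
    keeps common lowercase words ('nice', 'of') from firing as places.
    """

    def __init__(self, lexicon: dict[str, str]):
        self._phrases: dict[tuple[str, ...], str] = {}
        for phrase, tag in lexicon.items():
            if tag not in NER_TAGS:
                raise ValueError(f"lexicon phrase {phrase!r} has invalid tag {tag!r}")
            key = tuple(normalize_text(phrase).split())
            if key:
                self._phrases[key] = tag
        self._max_len = max((len(k) for k in self._phrases), default=0)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "LexiconTagger":
        lexicon: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            phrase, _, tag = line.partition("\t")
            lexicon[phrase.strip()] = tag.strip()
        return cls(lexicon)

    def tag(self, surfaces: Sequence[str]) -> list[str]:
        normalized = [normalize_text(s) for s in surfaces]
        tags = [OTHER] * len(surfaces)
        i = 0
        while i < len(surfaces):
            matched = 0
            matched_tag = OTHER
            for length in range(min(self._max_len, len(surfaces) - i), 0, -1):
                key = tuple(normalized[i:i + length])
                if key in self._phrases:
                    matched = length
                    matched_tag = self._phrases[key]
                    break
            if matched:
                for j in range(i, i + matched):
                    tags[j] = matched_tag
                i += matched
            else:
                i += 1
        return tags


# ---------------------------------------------------------------------------
# Sentence splitting and tokenization
# ---------------------------------------------------------------------------

#: Abbreviations that never terminate a sentence.
_ABBREVIATIONS = {
    "fig", "figs", "al", "e.g", "i.e", "approx", "ca", "cf", "vs", "etc",
    "dr", "prof", "mr", "mrs", "ms", "st", "no", "vol", "pp",
}

_SENT_BOUNDARY = re.compile(r"([.!?])(\s+)(?=[A-Z0-9(])")


def split_sentences(paragraph: str) -> list[str]:
    """Abbreviation-aware, parenthetical-aware rule-based sentence splitter."""
    text = paragraph
    boundaries = [0]
    for m in _SENT_BOUNDARY.finditer(text):
        end = m.end(1)
        before = text[:m.start(1)]
        # abbreviation check: word immediately before the period
        tail = re.search(r"([A-Za-z][A-Za-z.]*)$", before)
        if tail and tail.group(1).lower().rstrip(".") in _ABBREVIATIONS:
            continue
        # single initial like "J." (common in citations)
        if tail and len(tail.group(1)) == 1 and tail.group(1).isupper():
            continue
        # parenthetical rule: no split inside a short open parenthetical
        open_idx = before.rfind("(")
        if open_idx != -1 and before.count("(", open_idx) > before.count(")", open_idx):
            if m.start(1) - open_idx < PARENTHETICAL_NO_SPLIT_CHARS:
                continue
        boundaries.append(end)
    boundaries.append(len(text))
    sentences = []
    for a, b in zip(boundaries, boundaries[1:]):
        chunk = text[a:b].strip()
        if chunk:
            sentences.append(chunk)
    return sentences


_TOKEN_RE = re.compile(r"\w+(?:['’]\w+)?|[^\w\s]")

_PREPOSITIONS = {
    "in", "on", "at", "of", "to", "from", "by", "with", "for", "near", "upon",
}


def tokenize(sentence: str) -> list[str]:
    """Split a sentence into word and punctuation tokens."""
    return _TOKEN_RE.findall(sentence)


def _pos_tag(surface: str) -> str:
    """Minimal rule-based part-of-speech labelling.

    Downstream rules only need to distinguish proper nouns, numbers, and
    prepositions; everything else is labelled as a common word.
    """
    if re.fullmatch(r"\d+(\.\d+)?", surface):
        return "CD"
    if not surface[0].isalnum():
        return "PUNCT"
    if surface.lower() in _PREPOSITIONS:
        return "IN"
    if surface[0].isupper():
        return "NNP"
    return "NN"


def segment_and_tag(
    paragraph: str,
    tagger: EntityTagger,
    article_id: str = "",
    heading: Optional[str] = None,
    paragraph_index: int = 0,
) -> list[Sentence]:
    """Split a paragraph into tagged sentences.

    The paragraph is normalized, split into sentences and tokens, given
    part-of-speech labels, and run through the entity tagger. A tagger failure
    raises a StageError carrying the provenance so the caller can skip the
    paragraph and continue the corpus run.
    """
    normalized = normalize_text(paragraph)
    sentences: list[Sentence] = []
    for s_idx, raw in enumerate(split_sentences(normalized)):
        surfaces = tokenize(raw)
        if not surfaces:
            continue
        try:
            ner_tags = tagger.tag(surfaces)
        except Exception as exc:  # noqa: BLE001 — contract violation is a stage failure
            raise StageError(
                f"entity tagger failed: {exc}",
                provenance=(article_id, heading, paragraph_index, s_idx),
            ) from exc
        if len(ner_tags) != len(surfaces):
            raise StageError(
                "entity tagger returned wrong-length tag sequence",
                provenance=(article_id, heading, paragraph_index, s_idx),
            )
        tokens = [
            Token(surface=w, normalized=normalize_text(w), pos_tag=_pos_tag(w), ner_tag=t)
            for w, t in zip(surfaces, ner_tags)
        ]
        sentences.append(
            Sentence(
                tokens=tokens,
                raw_text=raw,
                article_id=article_id,
                heading=heading,
                paragraph_index=paragraph_index,
                sentence_index=s_idx,
            )
        )
    return sentences


# ---------------------------------------------------------------------------
# Candidate assembly
# ---------------------------------------------------------------------------

_NO_SPACE_BEFORE = {",", ")", ".", ";", ":", "?", "!"}
_NO_SPACE_AFTER = {"("}


def join_tokens(surfaces: Sequence[str]) -> str:
    """Join token surfaces with natural punctuation spacing.

    Candidate strings become geocoding queries, so there is no space before
    ','/')' and none after '('.
    """
    parts: list[str] = []
    for surf in surfaces:
        if parts and surf not in _NO_SPACE_BEFORE and parts[-1] not in _NO_SPACE_AFTER:
            parts.append(" ")
        parts.append(surf)
    return "".join(parts)


def _is_entity(tok: Token) -> bool:
    return tok.ner_tag != OTHER


def _is_bridge(tok: Token, profile: DomainProfile) -> bool:
    """Whether a non-entity token may appear between entities in a span."""
    low = tok.normalized.lower()
    return (
        low in profile.connector_words
        or low in profile.candidate_extension_lexicon
        or tok.surface in profile.state_abbreviations
        or tok.surface in {",", "(", ")"}
    )


def _edge_ok_left(tok: Token, profile: DomainProfile) -> bool:
    """Tokens absorbable at the left edge of a span (before the first entity):
    extension-lexicon words like cardinal directions ('Southern Russia')."""
    return tok.normalized.lower() in profile.candidate_extension_lexicon


def _edge_ok_right(tok: Token, profile: DomainProfile) -> bool:
    """Tokens absorbable at the right edge: extension words and state
    abbreviations ('Madison, WI')."""
    return (
        tok.normalized.lower() in profile.candidate_extension_lexicon
        or tok.surface in profile.state_abbreviations
    )


def span_is_valid(tokens: Sequence[Token], start: int, end: int, profile: DomainProfile) -> bool:
    """Validity predicate for a candidate span ``[start, end)``.

    A span is valid when it contains at least one entity token; every run of
    non-entity tokens strictly between entities is all-bridgeable and at most
    MAX_BRIDGE_GAP long; leading non-entity tokens (at most MAX_EDGE_RUN) are
    left-edge words; trailing non-entity tokens (at most MAX_EDGE_RUN) are
    right-edge words, a comma directly followed by a state abbreviation, or a
    ')' whose '(' lies within the span.
    """
    if start >= end:
        return False
    span = tokens[start:end]
    ent_positions = [i for i, t in enumerate(span) if _is_entity(t)]
    if not ent_positions:
        return False
    first_ent, last_ent = ent_positions[0], ent_positions[-1]
    if first_ent > MAX_EDGE_RUN or (len(span) - 1 - last_ent) > MAX_EDGE_RUN:
        return False
    for tok in span[:first_ent]:
        if not _edge_ok_left(tok, profile):
            return False
    gap = 0
    for tok in span[first_ent:last_ent]:
        if _is_entity(tok):
            gap = 0
        else:
            gap += 1
            if gap > MAX_BRIDGE_GAP or not _is_bridge(tok, profile):
                return False
    open_parens = sum(1 for t in span[: last_ent + 1] if t.surface == "(") - sum(
        1 for t in span[: last_ent + 1] if t.surface == ")"
    )
    i = last_ent + 1
    while i < len(span):
        tok = span[i]
        if tok.surface == ")" and open_parens > 0:
            open_parens -= 1
        elif tok.surface == "," and i + 1 < len(span) and span[i + 1].surface in profile.state_abbreviations:
            pass
        elif _edge_ok_right(tok, profile):
            pass
        else:
            return False
        i += 1
    return True


def assemble_candidates(sentence: Sentence, profile: DomainProfile) -> list[LocationCandidate]:
    """Form maximal location-candidate spans over a tagged sentence.

    Spans are grown greedily left-to-right: starting at each entity token not
    yet consumed, the span is extended rightward over further entities
    (bridging valid gaps), then over right-edge words, and leftward over
    left-edge words. The resulting candidates are non-overlapping, ordered,
    and each contains at least one entity token. On short sentences this
    construction provably coincides with brute-force enumeration of maximal
    valid spans.
    """
    tokens = sentence.tokens
    n = len(tokens)
    candidates: list[LocationCandidate] = []
    consumed_until = 0
    i = 0
    while i < n:
        if not _is_entity(tokens[i]):
            i += 1
            continue
        start = i
        end = i + 1
        # extend over consecutive entities
        while end < n and _is_entity(tokens[end]):
            end += 1
        # bridge to later entity groups
        while True:
            j = end
            gap = 0
            while j < n and not _is_entity(tokens[j]) and gap < MAX_BRIDGE_GAP and _is_bridge(tokens[j], profile):
                j += 1
                gap += 1
            if j < n and _is_entity(tokens[j]):
                end = j + 1
                while end < n and _is_entity(tokens[end]):
                    end += 1
            else:
                break
        # right-edge absorption (two-token lookahead covers ', WI' tails)
        while end < n:
            if span_is_valid(tokens, start, end + 1, profile):
                end += 1
            elif end + 1 < n and span_is_valid(tokens, start, end + 2, profile):
                end += 2
            else:
                break
        # left-edge absorption (never into a previous candidate)
        while start > consumed_until and span_is_valid(tokens, start - 1, end, profile):
            start -= 1
        surfaces = [t.surface for t in tokens[start:end]]
        candidates.append(
            LocationCandidate(
                span=(start, end),
                candidate_string=join_tokens(surfaces),
                tag_sequence=[t.ner_tag for t in tokens[start:end]],
                sentence=sentence,
            )
        )
        consumed_until = end
        i = end
    return candidates
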