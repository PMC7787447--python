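"""Parse plain-text and structured-XML article representations.

Scientific-article PDFs are converted upstream into two representations: a
plain UTF-8 text file and a JATS/NLM-style XML file. Both are parsed here into
a common :class:`ArticleDocument` model so downstream stages can choose
whichever representation exposes usable section headings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from lxml import etree

from scigeo.errors import ArticleParseError, DocumentEmptyError

logger = logging.getLogger(__name__)

#: Cap on the leading span of a plain-text paragraph exposed for heading
#: matching. Headings converted from PDF usually occupy one short line; the
#: cap avoids matching words in mid-prose.
PARAGRAPH_BEGINNING_CAP = 120

#: Case-insensitive whole-line patterns that mark the start of a references
#: section in plain text (and reference-like headings in XML).
DEFAULT_REFERENCES_PATTERNS = (
    r"references?",
    r"bibliography",
    r"literature\s+cited",
)


@dataclass
class Section:
    """One headed block of an article.

    Plain-text documents that expose no headings are represented as a single
    synthetic section whose ``heading`` is ``None``.
    """

    heading: Optional[str]
    paragraphs: list[str] = field(default_factory=list)
    is_references: bool = False


@dataclass
class ArticleDocument:
    """A parsed article: title plus ordered sections of paragraphs."""

    article_id: str
    title: Optional[str]
    sections: list[Section]
    source_kind: str  # "plain_text" | "structured_xml"

    def paragraphs(self) -> list[str]:
        """All paragraph strings in document order."""
        return [p for sec in self.sections for p in sec.paragraphs]


def paragraph_beginning(paragraph: str, cap: int = PARAGRAPH_BEGINNING_CAP) -> str:
    """The leading span of a paragraph used for heading matching.

    Defined as the first line of the paragraph, truncated to ``cap``
    characters.
    """
    first_line = paragraph.lstrip().split("\n", 1)[0]
    return first_line[:cap]


def matches_references_heading(text: str, patterns: Iterable[str] = DEFAULT_REFERENCES_PATTERNS) -> bool:
    """Whether ``text`` is (only) a references-section heading."""
    stripped = text.strip().rstrip(":.").strip()
    return any(re.fullmatch(pat, stripped, flags=re.IGNORECASE) for pat in patterns)


def _decode(data: Union[str, bytes], article_id: str) -> str:
    if isinstance(data, bytes):
        try:
            return data.decode("utf-8")
        except UnicodeDecodeError:
            logger.warning("%s: undecodable bytes replaced", article_id)
            return data.decode("utf-8", errors="replace")
    return data


def parse_plain_text(text: Union[str, bytes], article_id: str = "article") -> ArticleDocument:
    """Parse a plain-text article into paragraphs delimited by blank lines.

    The document becomes one synthetic (untitled) section; if a paragraph is a
    references heading, that paragraph and all following ones are collected
    into a references-flagged section.

    Raises
    ------
    DocumentEmptyError
        If the input is empty or whitespace-only.
    """
    text = _decode(text, article_id)
    if not text or not text.strip():
        raise DocumentEmptyError(article_id, "plain-text input is empty")

    raw_paragraphs = [p.strip() for p in re.split(r"\n\s*\n", text)]
    paragraphs = [p for p in raw_paragraphs if p]

    body = Section(heading=None, paragraphs=[])
    sections = [body]
    in_references = False
    for para in paragraphs:
        if not in_references and matches_references_heading(paragraph_beginning(para)):
            in_references = True
            sections.append(Section(heading=para.split("\n", 1)[0].strip(), is_references=True))
            continue
        if in_references:
            sections[-1].paragraphs.append(para)
        else:
            body.paragraphs.append(para)

    return ArticleDocument(
        article_id=article_id, title=None, sections=sections, source_kind="plain_text"
    )


# JATS and the common NLM converter dialect both use <sec>/<title>/<p>;
# title lives under front/article-meta/title-group/article-title.
_TITLE_XPATHS = (
    "front/article-meta/title-group/article-title",
    "front//article-title",
    "title",
)


def _element_text(el: etree._Element) -> str:
    return " ".join("".join(el.itertext()).split())


def _walk_secs(parent: etree._Element, out: list[Section]) -> None:
    """Flatten nested <sec> elements depth-first, keeping every heading."""
    heading_el = parent.find("title")
    heading = _element_text(heading_el) if heading_el is not None else None
    section = Section(
        heading=heading,
        is_references=bool(heading and matches_references_heading(heading)),
    )
    for child in parent:
        if child.tag == "p":
            text = _element_text(child)
            if text:
                section.paragraphs.append(text)
        elif child.tag == "sec":
            continue  # handled below, after this section's own paragraphs
        elif child.tag == "title":
            continue
        else:
            logger.debug("skipping unknown element <%s>", child.tag)
    if section.paragraphs or heading is not None:
        out.append(section)
    for child in parent:
        if child.tag == "sec":
            _walk_secs(child, out)


def parse_structured_article(
    source: Union[str, bytes, Path], article_id: str = "article"
) -> ArticleDocument:
    """Parse a JATS/NLM-style XML article.

    Accepts a path, an XML string, or raw bytes. Headings and paragraph text
    are extracted in document order; nested sections are flattened depth-first
    with every heading preserved.

    Raises
    ------
    ArticleParseError
        On malformed XML.
    DocumentEmptyError
        When the body carries no paragraph text.
    """
    if isinstance(source, Path):
        data = source.read_bytes()
    elif isinstance(source, str) and "<" not in source:
        data = Path(source).read_bytes()
    else:
        data = source.encode("utf-8") if isinstance(source, str) else source

    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ArticleParseError(article_id, f"malformed XML: {exc}") from exc

    title: Optional[str] = None
    for xp in _TITLE_XPATHS:
        found = root.findall(xp)
        if found:
            title = _element_text(found[0]) or None
            break

    body = root.find("body")
    if body is None:
        body = root if root.tag == "body" else None
    sections: list[Section] = []
    if body is not None:
        # top-level loose <p> (outside any <sec>) become an untitled section
        loose = Section(heading=None)
        for child in body:
            if child.tag == "p":
                text = _element_text(child)
                if text:
                    loose.paragraphs.append(text)
        if loose.paragraphs:
            sections.append(loose)
        for sec in body.findall("sec"):
            _walk_secs(sec, sections)

    if not any(s.paragraphs for s in sections):
        raise DocumentEmptyError(article_id, "XML body contains no paragraph text")

    return ArticleDocument(
        article_id=article_id, title=title, sections=sections, source_kind="structured_xml"
    )
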