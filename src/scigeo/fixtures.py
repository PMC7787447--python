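"""Synthetic corpora, toy gazetteers, and mock-tagger lexicons.

Everything the pipeline consumes can be generated here deterministically from
a seed, so every stage is testable offline. Articles emulate the two corpus
styles the pipeline is designed for: an "orchards" template (ecology field
studies with study-site sections, located titles, and company parentheticals
in the methods) and a "cancer" template (biomedical studies with
patient/sample sections naming hospitals and cities, and a quality mix that
includes articles reporting no location at all). All place names, hospitals,
people, and companies are synthetic; the generated gazetteer is the ground
truth for geocoding.

Planted relevant locations are recorded exhaustively in the annotation
output, each appearing verbatim in exactly one targeted-section sentence (or
the title) of its article. Company distractors always contain a discard word,
so the full filter removes them — this is what makes the noise-free
perfect-score oracle constructible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union
from xml.sax.saxutils import escape

from scigeo.errors import ScigeoError
from scigeo.evaluation import GroundTruthAnnotation, TruthLocation
from scigeo.geocoding import Gazetteer, GazetteerRecord

# ---------------------------------------------------------------------------
# Synthetic name pools (all invented; disjoint by construction)
# ---------------------------------------------------------------------------

_COUNTRIES = [
    # (record id, name, code)
    ("C01", "Veridia", "VE"),
    ("C02", "Norland", "NO"),
    ("C03", "Austrora", "AU"),
    ("C04", "Meridonia", "ME"),
    ("C05", "Zephyria", "ZE"),
    ("C06", "Caldora", "CA"),
]

_ADMIN_AREAS = ["Westmark", "Eastvale", "Highmoor", "Lowfen", "Midreach", "Suncrest",
                "Greyholm", "Fernland", "Stonewick", "Brightshire", "Coldmere", "Ashdale"]

#: Localities planted as relevant study/sample locations.
_TRUTH_LOCALITIES = [
    "Riverton", "Lakemouth", "Thornbury", "Elderglen", "Maplewick", "Hollowbrook",
    "Silverford", "Crowhurst", "Bramblefield", "Ostmere", "Veyton", "Quillbridge",
    "Darrowvale", "Finchley Hollow", "Galeport", "Wrenfield", "Ivoryhill", "Tarnstead",
    "Umberly", "Pinecrest Flats", "Saltmarsh", "Kestrelmoor", "Ryehaven", "Duskford",
]

#: Localities used only inside company-address distractors.
_DISTRACTOR_LOCALITIES = [
    "Gearford", "Boltham", "Coppervale", "Smeltington", "Wireton", "Lathbury",
    "Pistonby", "Riveter Falls",
]

_HOSPITALS = [
    "Veridia General Hospital", "Norland University Hospital", "Saint Elm Clinic",
    "Austrora Cancer Institute", "Meridonia Medical Center", "Zephyria Memorial Hospital",
]

_SURNAMES = ["Ashworth", "Bellanger", "Cramond", "Delacroix", "Eberhart", "Fairwood",
             "Grimsbane", "Holloway"]

_COMPANIES = ["Acme", "Gentech", "Chromaline", "Probexa", "Nucleomix", "Vitrolabs"]

_INTRO_SENTENCES = [
    "Agricultural intensification has altered habitats worldwide over recent decades.",
    "Understanding these dynamics requires long term observational data.",
    "Previous work has documented declines across multiple taxa.",
    "Genomic profiling has transformed our understanding of tumour biology.",
    "Copy number alterations are a hallmark of many solid tumours.",
]

_RESULTS_SENTENCES = [
    "Species richness differed significantly between treatments.",
    "Abundance declined with increasing management intensity.",
    "Recurrent gains and losses were observed across chromosomes.",
    "Hierarchical clustering separated the two groups clearly.",
]

_RELEVANT_TEMPLATES = [
    "The study was conducted in {loc}.",
    "Field sites were established in {loc}.",
    "Sampling took place in {loc}.",
    "All surveys were carried out in {loc}.",
]

_RELEVANT_TEMPLATES_CANCER = [
    "Specimens were obtained from patients treated at {loc}.",
    "All samples were collected at {loc}.",
    "Patients were recruited at {loc}.",
]

_COMPANY_TEMPLATES = [
    "Reagents were purchased commercially ({company} Inc, {loc}).",
    "Instruments were supplied by a vendor ({company} Inc, {loc}).",
]

_CITATION_TEMPLATES = [
    "Protocols followed established procedures ({surname} {year}).",
    "Site selection followed earlier surveys ({surname} {year}).",
]

#: Background mentions planted in the introduction: locations that are *not*
#: study sites (prior-work context). Invisible to the full pipeline, which
#: never targets the introduction, but extracted when targeting is disabled.
_BACKGROUND_TEMPLATES = [
    "Earlier studies in {loc} reported comparable patterns.",
    "Similar declines were documented in {loc}.",
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic corpus.

    The same seed and spec always produce byte-identical outputs.
    """

    seed: int = 0
    n_articles: int = 10
    relevant_per_article: tuple[int, int] = (1, 3)
    distractors_per_article: tuple[int, int] = (0, 2)
    heading_style: str = "both"  # "xml" | "plain" | "both"
    profile_id: str = "orchards"  # template: "orchards" | "cancer"
    background_mentions_per_article: tuple[int, int] = (0, 1)

    def __post_init__(self):
        if self.n_articles < 1:
            raise ScigeoError("n_articles must be >= 1")
        for lo, hi in (
            self.relevant_per_article,
            self.distractors_per_article,
            self.background_mentions_per_article,
        ):
            if lo < 0 or hi < lo:
                raise ScigeoError("count ranges must satisfy 0 <= lo <= hi")
        if self.heading_style not in ("xml", "plain", "both"):
            raise ScigeoError(f"unknown heading_style {self.heading_style!r}")
        if self.profile_id not in ("orchards", "cancer"):
            raise ScigeoError(f"unknown fixture template {self.profile_id!r}")


@dataclass
class SyntheticArticle:
    article_id: str
    title: str
    xml_text: Optional[str]
    plain_text: Optional[str]
    truths: list[TruthLocation]
    location_quality: str


@dataclass
class SyntheticCorpus:
    articles: list[SyntheticArticle]
    gazetteer: Gazetteer
    gazetteer_tsv: str
    lexicon: dict[str, str]
    lexicon_tsv: str
    annotations: dict[str, GroundTruthAnnotation]
    annotations_tsv: str

    def write(self, out_dir: Union[str, Path]) -> Path:
        """Write the corpus file tree (XML/, txt/, gazetteer, lexicon, annotations)."""
        out = Path(out_dir)
        (out / "xml").mkdir(parents=True, exist_ok=True)
        (out / "txt").mkdir(parents=True, exist_ok=True)
        for art in self.articles:
            if art.xml_text is not None:
                (out / "xml" / f"{art.article_id}.xml").write_text(art.xml_text, encoding="utf-8")
            if art.plain_text is not None:
                (out / "txt" / f"{art.article_id}.txt").write_text(art.plain_text, encoding="utf-8")
        (out / "gazetteer.tsv").write_text(self.gazetteer_tsv, encoding="utf-8")
        (out / "lexicon.tsv").write_text(self.lexicon_tsv, encoding="utf-8")
        (out / "annotations.tsv").write_text(self.annotations_tsv, encoding="utf-8")
        return out


def build_gazetteer(rng: random.Random) -> tuple[Gazetteer, str]:
    """Build the synthetic gazetteer: countries, admin areas, localities,
    hospitals (points of interest), with deterministic populations."""
    rows: list[GazetteerRecord] = []
    for cid, name, code in _COUNTRIES:
        rows.append(
            GazetteerRecord(
                record_id=cid, primary_name=name, alternate_names=frozenset(),
                feature_class="C", latitude=round(rng.uniform(-60, 60), 4),
                longitude=round(rng.uniform(-170, 170), 4),
                population=rng.randrange(1_000_000, 50_000_000), country_code=code,
                admin_path=(),
            )
        )
    admin_records = []
    for i, admin in enumerate(_ADMIN_AREAS):
        cid, country, code = _COUNTRIES[i % len(_COUNTRIES)]
        rec = GazetteerRecord(
            record_id=f"A{i:02d}", primary_name=admin, alternate_names=frozenset(),
            feature_class="A", latitude=round(rng.uniform(-60, 60), 4),
            longitude=round(rng.uniform(-170, 170), 4),
            population=rng.randrange(100_000, 5_000_000), country_code=code,
            admin_path=(country,),
        )
        admin_records.append(rec)
        rows.append(rec)
    for i, locality in enumerate(_TRUTH_LOCALITIES + _DISTRACTOR_LOCALITIES):
        admin = admin_records[i % len(admin_records)]
        alt = frozenset({locality.split()[0][:3].upper() + "X"}) if i % 7 == 0 else frozenset()
        rows.append(
            GazetteerRecord(
                record_id=f"L{i:03d}", primary_name=locality, alternate_names=alt,
                feature_class="P", latitude=round(rng.uniform(-60, 60), 4),
                longitude=round(rng.uniform(-170, 170), 4),
                population=rng.randrange(1_000, 900_000), country_code=admin.country_code,
                admin_path=(admin.primary_name,) + admin.admin_path,
            )
        )
    for i, hospital in enumerate(_HOSPITALS):
        locality_rec = rows[len(_COUNTRIES) + len(_ADMIN_AREAS) + i]
        rows.append(
            GazetteerRecord(
                record_id=f"S{i:02d}", primary_name=hospital, alternate_names=frozenset(),
                feature_class="S", latitude=locality_rec.latitude,
                longitude=locality_rec.longitude, population=0,
                country_code=locality_rec.country_code,
                admin_path=(locality_rec.primary_name,) + locality_rec.admin_path,
            )
        )
    tsv_lines = ["\t".join(["#id", "name", "alternate_names", "feature_class",
                            "latitude", "longitude", "population", "country_code",
                            "admin_path"])]
    for rec in rows:
        tsv_lines.append(
            "\t".join(
                [
                    rec.record_id, rec.primary_name, "|".join(sorted(rec.alternate_names)),
                    rec.feature_class, str(rec.latitude), str(rec.longitude),
                    str(rec.population), rec.country_code, "|".join(rec.admin_path),
                ]
            )
        )
    return Gazetteer(rows), "\n".join(tsv_lines) + "\n"


_TAG_PRECEDENCE = {"LOCATION": 0, "ORGANIZATION": 1, "PERSON": 2, "OTHER": 3}


def build_mock_lexicon(
    gazetteer: Gazetteer, extra_entities: Optional[dict[str, str]] = None
) -> tuple[dict[str, str], str]:
    """Build the deterministic tagger lexicon.

    Every gazetteer name (primary and alternate) maps to LOCATION; extra
    entities add hospital/university names as ORGANIZATION and person names
    as PERSON. Duplicate names keep the highest-precedence tag (LOCATION
    over ORGANIZATION over PERSON). Returns the lexicon and its TSV
    serialization in deterministic order.
    """
    lexicon: dict[str, str] = {}

    def add(phrase: str, tag: str) -> None:
        current = lexicon.get(phrase)
        if current is None or _TAG_PRECEDENCE[tag] < _TAG_PRECEDENCE[current]:
            lexicon[phrase] = tag

    for rec in gazetteer.records:
        add(rec.primary_name, "LOCATION")
        for alt in sorted(rec.alternate_names):
            add(alt, "LOCATION")
    for phrase, tag in sorted((extra_entities or {}).items()):
        add(phrase, tag)
    tsv = "".join(f"{phrase}\t{tag}\n" for phrase, tag in sorted(lexicon.items()))
    return lexicon, tsv


def default_extra_entities(template: str = "orchards") -> dict[str, str]:
    """Person and company entities for the mock tagger (distractor support)."""
    extras: dict[str, str] = {}
    for surname in _SURNAMES:
        extras[surname] = "PERSON"
    for company in _COMPANIES:
        extras[f"{company} Inc"] = "ORGANIZATION"
    return extras


def _article_xml(title: str, sections: Sequence[tuple[str, list[str]]]) -> str:
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        "<article>",
        "  <front><article-meta><title-group>",
        f"    <article-title>{escape(title)}</article-title>",
        "  </title-group></article-meta></front>",
        "  <body>",
    ]
    for heading, paragraphs in sections:
        parts.append(f"    <sec><title>{escape(heading)}</title>")
        for p in paragraphs:
            parts.append(f"      <p>{escape(p)}</p>")
        parts.append("    </sec>")
    parts.append("  </body>")
    parts.append("</article>")
    return "\n".join(parts) + "\n"


def _article_plain(title: str, sections: Sequence[tuple[str, list[str]]]) -> str:
    blocks = [title]
    for heading, paragraphs in sections:
        blocks.append(heading)
        blocks.extend(paragraphs)
    return "\n\n".join(blocks) + "\n"


def generate_corpus(spec: FixtureSpec) -> SyntheticCorpus:
    """Generate a deterministic synthetic corpus from a fixture spec."""
    rng = random.Random(spec.seed)
    gazetteer, gazetteer_tsv = build_gazetteer(random.Random(spec.seed + 1))
    lexicon, lexicon_tsv = build_mock_lexicon(gazetteer, default_extra_entities(spec.profile_id))

    by_name = {rec.primary_name: rec for rec in gazetteer.records}
    locality_recs = [by_name[n] for n in _TRUTH_LOCALITIES]
    distractor_recs = [by_name[n] for n in _DISTRACTOR_LOCALITIES]
    hospital_recs = [by_name[n] for n in _HOSPITALS]

    cancer = spec.profile_id == "cancer"
    articles: list[SyntheticArticle] = []
    annotations: dict[str, GroundTruthAnnotation] = {}

    for idx in range(spec.n_articles):
        article_id = f"art{idx:03d}"
        quality = "good"
        if cancer and rng.random() < 0.2:
            quality = rng.choice(["none", "bad"])

        truths: list[TruthLocation] = []
        relevant_sentences: list[str] = []
        n_relevant = rng.randint(*spec.relevant_per_article)

        title_truth: Optional[TruthLocation] = None
        if cancer:
            title = rng.choice(
                [
                    "Genomic imbalances in primary tumours detected by comparative hybridization",
                    "Recurrent copy number alterations in carcinoma samples",
                    "Chromosomal profiling of tumour specimens by array analysis",
                ]
            )
        else:
            title_loc = rng.choice(locality_recs)
            title = f"Biodiversity and management of fruit orchards in {title_loc.primary_name}"
            title_truth = TruthLocation(
                truth_string=title_loc.primary_name, record_id=title_loc.record_id,
                latitude=title_loc.latitude, longitude=title_loc.longitude,
            )

        if quality == "good":
            if cancer:
                picks = rng.sample(hospital_recs, min(n_relevant, len(hospital_recs)))
                templates = _RELEVANT_TEMPLATES_CANCER
            else:
                # the title locality is excluded so each planted location
                # appears exactly once in the article
                pool = [r for r in locality_recs if r.primary_name not in title]
                picks = rng.sample(pool, min(n_relevant, len(pool)))
                templates = _RELEVANT_TEMPLATES
            for rec in picks:
                if not cancer and rng.random() < 0.5:
                    phrase = f"{rec.primary_name}, {rec.admin_path[-1]}"
                else:
                    phrase = rec.primary_name
                relevant_sentences.append(rng.choice(templates).format(loc=phrase))
                truths.append(
                    TruthLocation(
                        truth_string=phrase, record_id=rec.record_id,
                        latitude=rec.latitude, longitude=rec.longitude,
                    )
                )
        elif quality == "bad":
            relevant_sentences.append(
                "Sample provenance was described in an earlier report from our group."
            )

        if title_truth is not None and quality == "good":
            truths.insert(0, title_truth)
        elif title_truth is not None:
            # vague/no-location articles in the orchards template still get a
            # located title; keep the annotation consistent with it
            truths.insert(0, title_truth)

        distractor_sentences: list[str] = []
        n_distractors = rng.randint(*spec.distractors_per_article)
        for _ in range(n_distractors):
            if rng.random() < 0.5:
                rec = rng.choice(distractor_recs)
                distractor_sentences.append(
                    rng.choice(_COMPANY_TEMPLATES).format(
                        company=rng.choice(_COMPANIES),
                        loc=f"{rec.primary_name}, {rec.admin_path[-1]}",
                    )
                )
            else:
                distractor_sentences.append(
                    rng.choice(_CITATION_TEMPLATES).format(
                        surname=rng.choice(_SURNAMES), year=rng.randint(1980, 2015)
                    )
                )

        methods_sentences = relevant_sentences + distractor_sentences
        rng.shuffle(methods_sentences)
        if not methods_sentences:
            methods_sentences = ["Standard laboratory procedures were followed throughout."]

        intro_sentences = rng.sample(_INTRO_SENTENCES, 2)
        for _ in range(rng.randint(*spec.background_mentions_per_article)):
            rec = rng.choice(distractor_recs)
            intro_sentences.append(
                rng.choice(_BACKGROUND_TEMPLATES).format(
                    loc=f"{rec.primary_name}, {rec.admin_path[-1]}"
                )
            )

        methods_heading = "Patients and samples" if cancer else "Materials and methods"
        sections = [
            ("Introduction", [" ".join(intro_sentences)]),
            (methods_heading, [" ".join(methods_sentences)]),
            ("Results", [" ".join(rng.sample(_RESULTS_SENTENCES, 2))]),
            (
                "References",
                [
                    f"{rng.choice(_SURNAMES)} J ({rng.randint(1980, 2015)}) Prior findings. "
                    "Journal of Synthetic Studies 12: 34-56."
                ],
            ),
        ]

        xml_text = _article_xml(title, sections) if spec.heading_style in ("xml", "both") else None
        plain_text = (
            _article_plain(title, sections) if spec.heading_style in ("plain", "both") else None
        )

        articles.append(
            SyntheticArticle(
                article_id=article_id, title=title, xml_text=xml_text,
                plain_text=plain_text, truths=truths, location_quality=quality,
            )
        )
        annotations[article_id] = GroundTruthAnnotation(
            article_id=article_id, truth_locations=list(truths), location_quality=quality
        )

    header = "\t".join(
        ["article_id", "truth_string", "truth_record_id", "truth_lat", "truth_lon",
         "location_quality"]
    )
    ann_lines = [header]
    for art in articles:
        if art.truths:
            for t in art.truths:
                ann_lines.append(
                    "\t".join(
                        [
                            art.article_id, t.truth_string, t.record_id or "",
                            "" if t.latitude is None else str(t.latitude),
                            "" if t.longitude is None else str(t.longitude),
                            art.location_quality,
                        ]
                    )
                )
        else:
            ann_lines.append(
                "\t".join([art.article_id, "", "", "", "", art.location_quality])
            )

    return SyntheticCorpus(
        articles=articles,
        gazetteer=gazetteer,
        gazetteer_tsv=gazetteer_tsv,
        lexicon=lexicon,
        lexicon_tsv=lexicon_tsv,
        annotations=annotations,
        annotations_tsv="\n".join(ann_lines) + "\n",
    )
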