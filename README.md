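# scigeo

Extract, filter, and geocode the *relevant* geographic locations — study
sites, field plots, patient and sample provenance — from scientific-article
full text.

Scientific articles are full of place names, but most of them do not say
where the science happened: company addresses in reagent parentheticals
("... Carl Zeiss GmbH, Jena, Germany"), cited authors' affiliations, and
background mentions all outnumber the handful of locations a human annotator
would record for a meta-analysis. `scigeo` implements a fully automatic
pipeline that targets the article portions likely to describe study or
sample locations, recognizes location mentions there, filters out the
irrelevant ones with transparent rules, and resolves the survivors against a
gazetteer into structured spatial records — each retained location keeping
the sentence it was found in.

## Pipeline

1. **Parse** — plain-text and JATS/NLM-style XML article representations are
   read into a common document model (`corpus_io`). Both representations can
   coexist for one article; XML is preferred whenever its section headings
   are usable.
2. **Target** — a *domain profile* (heading patterns, lexicons, keep/discard
   word lists) selects methods / study-site / patient sections, and
   optionally the title (`section_targeting`). Two built-in profiles ship:
   `orchards` (ecology field studies) and `cancer` (biomedical studies);
   every list is overridable from YAML.
3. **Identify** — targeted text is normalized, split into sentences, and run
   through a pluggable 4-class entity tagger (LOCATION / PERSON /
   ORGANIZATION / OTHER). Any token span containing an entity becomes a
   location candidate, with entities bridged across connector words, commas,
   parentheses, state abbreviations, and cardinal-direction/feature-type
   words, so qualified strings like `Nancy (East of France)` stay whole
   (`location_identification`). This stage optimizes recall.
4. **Filter** — rules restore precision: candidates with no LOCATION tag,
   discard words (`Inc`, `GmbH`, ...), or citation/company token patterns
   are rejected; keep words (`University`, `Hospital`, ...) override the
   rejections. Retained strings are cleaned of trailing prepositions and
   punctuation and deduplicated per article (`location_filtering`).
5. **Geocode** — each cleaned string is resolved through a pluggable
   backend. The bundled offline backend ranks gazetteer records by match
   class (exact primary name > exact alternate > token containment), then
   population, then record id; qualified queries (`Paris, Texas`) are
   constrained by the containment hierarchy (`geocoding`).
6. **Report** — records are written as JSON-lines, CSV, and a GeoJSON
   FeatureCollection (one point per geocoded record, optionally labelled
   TP/FP against ground truth) (`reporting_geo`).

## Evaluation model

Two units of evaluation are implemented (`evaluation`):

- **Location unit** — each extracted string counts once:
  *extraction precision* = TP / (TP+FP) over the strings;
  *geocoding accuracy* = correct geocodes among true-positive strings;
  *full-pipeline precision* scores the final geocoded output, with wrongly
  extracted strings that return no geocode result counted as true negatives
  (excluded from the denominator).
- **Article unit** — per-article precision and recall scored out of 1, then
  averaged over the corpus so multi-site articles are not over-weighted, and
  combined as F1 = 2PR/(P+R).

An error taxonomy (`tally_errors`) attributes each end-to-end failure to its
main source: NER error, text portion not extracted, wrong/no geocode result,
comma group, candidate filtering error, non-standard headings, other.

Ablation switches expose the three reduced variants used to measure each
stage's contribution: *no extract* (whole article minus references),
*locations only* (ignore person/organization tags), *no filter*.

## Worked example

Generate a small synthetic corpus (articles, gazetteer, tagger lexicon,
annotations all derived from one seed), run the pipeline, and score it:

```python
from scigeo import parse_structured_article
from scigeo.fixtures import FixtureSpec, generate_corpus
from scigeo.geocoding import GazetteerBackend, Geocoder
from scigeo.location_identification import LexiconTagger
from scigeo.pipeline_orchestration import PipelineConfig, evaluate_run, run_corpus
from scigeo.section_targeting import orchards_profile

corpus = generate_corpus(FixtureSpec(seed=7, n_articles=3, distractors_per_article=(1, 2)))
docs = [(parse_structured_article(a.xml_text, a.article_id), None) for a in corpus.articles]

config = PipelineConfig(profile=orchards_profile())
tagger = LexiconTagger(corpus.lexicon)
geocoder = Geocoder(GazetteerBackend(corpus.gazetteer))
records, rejects, summary = run_corpus(docs, config, tagger, geocoder)

for rec in records:
    print(f"{rec.article_id}  {rec.location_string!r:30s} {rec.heading:22s} "
          f"-> {rec.geocode.formatted_name} ({rec.geocode.latitude}, {rec.geocode.longitude})")
print()
print(evaluate_run(records, corpus.annotations).as_text())
```

Output:

```
art000  'Maplewick'                    TITLE                  -> Maplewick, Midreach, Zephyria (36.9746, 121.2855)
art000  'Kestrelmoor, Meridonia'       Materials and methods  -> Kestrelmoor, Brightshire, Meridonia (18.9849, -128.9454)
art000  'Finchley Hollow, Norland'     Materials and methods  -> Finchley Hollow, Eastvale, Norland (8.2951, 137.7451)
art001  'Crowhurst'                    TITLE                  -> Crowhurst, Fernland, Norland (-9.1918, -41.8451)
art001  'Lakemouth'                    Materials and methods  -> Lakemouth, Eastvale, Norland (54.0, 116.7876)
art002  'Umberly'                      TITLE                  -> Umberly, Greyholm, Veridia (36.924, 1.6739)
art002  'Galeport, Austrora'           Materials and methods  -> Galeport, Highmoor, Austrora (-10.7879, -18.3419)
art002  'Quillbridge'                  Materials and methods  -> Quillbridge, Ashdale, Caldora (-40.7189, -130.3957)

location unit:
  extraction precision    1.000
  geocoding accuracy      1.000
  full pipeline precision 1.000
article unit:
  precision 1.000  recall 1.000  F1 1.000
```

Each line is one extracted content location: the article it came from, the
string as it appeared in the text, the section heading (titles are flagged
`TITLE`), and the geocoded result — the fully qualified name and the point
coordinates from the gazetteer. The company parentheticals and citations the
generator planted were rejected by the filter (they appear in `rejects` with
their rejection reasons), so every metric is 1.000 on this corpus.

The same pipeline is available from a shell:

```bash
scigeo fixtures --seed 7 --n-articles 3 --out corpus/
scigeo run --xml-dir corpus/xml --gazetteer corpus/gazetteer.tsv \
           --lexicon corpus/lexicon.tsv --profile orchards --out out/
scigeo evaluate --records out/records.jsonl --truth corpus/annotations.tsv
```

## Limitations

The synthetic fixtures exercise the pipeline's logic, not the messiness of
real PDF-converted text; see `docs/methods.md` for what the generator does
and does not emulate, the tunable parameters, and the design decisions
behind the candidate-assembly and disambiguation rules. PDF conversion
itself, NER model training, coordinate-string parsing, and compositional
descriptions ("30 km from Florence") are out of scope — the latter are
retained only through the sentence context attached to every record.
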