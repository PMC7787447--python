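# Methods

This note records the models, rules, and parameter choices behind `scigeo`,
the assumptions they rest on, and what the test suite does and does not
establish.

## Task and model

The task is to extract the *relevant* locations of a scientific article —
where field work was done, where patients or samples came from — rather than
every toponym the text mentions. The pipeline's underlying assumption is
that relevant locations are a small subset of all location mentions and that
two signals separate them from the rest: *where* they occur (methods,
study-site, patient/sample sections, and in some domains the title) and
*how* they occur (as place-name strings, not as company addresses or
citation fragments). Section targeting encodes the first signal; the
candidate filter encodes the second. Both are configuration, not code: a
`DomainProfile` carries the heading patterns, connector/extension lexicons,
and keep/discard word lists for a corpus, and transplanting the pipeline to
a new domain means writing a new profile.

## Document parsing

Articles arrive as plain UTF-8 text and/or JATS/NLM-style XML (the outputs
of standard PDF converters; the conversion itself is out of scope). Both are
parsed into one document model. For plain text, paragraphs are delimited by
blank lines — the converters we target emit this layout, though it is not
guaranteed — and a paragraph's "beginning" (first line, capped at 120
characters) stands in for a heading, since headings converted from PDF
usually occupy one short line. A references section is recognized by
case-insensitive whole-line match of {references, bibliography, literature
cited} and excluded from whole-article processing. XML is preferred whenever
at least one profile heading matches its section tree; plain text is the
fallback for articles whose XML conversion produced no usable headings. In
the plain-text fallback, a matched heading claims the following paragraphs
up to the next heading-like paragraph (all-caps, numbered, or a single short
line without a terminal period), capped at 10 paragraphs — plain text has no
section tree, so the span must be bounded heuristically.

## Candidate identification

Text is normalized (NFKD compatibility decomposition, diacritics stripped,
whitespace collapsed; idempotent), split into sentences by an
abbreviation-aware rule splitter (scientific abbreviations such as `Fig.`,
`et al.`, `e.g.`, `ca.` never end a sentence; boundaries are suppressed
inside parentheticals shorter than 60 characters so coordinate groups stay
in one sentence), tokenized, and tagged.

The entity tagger is a contract: token surfaces in, one tag per token out of
{LOCATION, PERSON, ORGANIZATION, OTHER}, pure and deterministic. The package
ships a lexicon tagger (longest-phrase match over a phrase→tag table) that
serves both as the deterministic test tagger and as a usable gazetteer-based
tagger; adapters for pretrained 3-class NER models implement the same
contract.

Candidate assembly keeps any maximal token span containing at least one
entity token. Non-entity tokens may appear inside a span only as *bridges* —
connector words ({in, upon, of, at, near, the} by default), commas,
parentheses, two-letter US state abbreviations, and the profile's extension
lexicon (cardinal directions and feature-type words for the ecology profile;
empty for the biomedical one) — in runs of at most 3, which prevents
whole-sentence candidates in entity-dense text. Spans may additionally
absorb up to 2 untagged edge words: extension words on the left ("southern
France"), extension words, state abbreviations, or a comma+state pair on the
right ("Madison, WI"), plus a closing parenthesis whose opener lies inside
the span ("Nancy (East of France)"). The edge cap is what makes maximal
valid spans provably disjoint, so the greedy left-to-right construction
coincides with brute-force enumeration of maximal valid spans — the
acceptance suite checks this equivalence on 1,000 random tagged sentences.
Candidate strings are joined with natural punctuation spacing because they
become geocoding queries.

## Filtering and cleaning

The filter applies, in order: (1) keep-word override — candidates containing
{University, Institute, Hospital, Medical School, Centre, Center, Clinic}
always survive, because institutions are archetypal relevant locations in
biomedical corpora even when taggers label them organizations; (2)
discard-word rejection ({Inc, Ltd, GmbH, Corp, Co., LLC, S.A., AG, KGaA}
variants — company-address markers); (3) rejection of spans with no
LOCATION-tagged token; (4) token (tag, word) combination rules — a
PERSON-tagged token immediately before a year-like token (a citation), and
an all-ORGANIZATION parenthetical following a product-like capitalized token
(a vendor). The rule table is deliberately small and user-extensible; keep
beats discard because the filter's purpose is precision *without* losing the
institutional locations that matter. Comma-separated place sequences are
kept as one candidate; this reproduces a known failure mode (distinct towns
merged into one qualified string) that is accepted in exchange for keeping
genuinely qualified strings together.

Cleaning strips trailing connector words, commas, periods, and dangling
parentheses to a fixed point (idempotent, never lengthening). Kept locations
are deduplicated case-insensitively per article before geocoding, with
duplicate counts retained; evaluation operates on the deduplicated set.

Two ablations mirror the pipeline's sensitivity experiments: *no extract*
routes the whole article (minus references) into identification; *locations
only* keeps only LOCATION-tagged tokens (truncating spans to them); *no
filter* passes every candidate through.

## Geocoding

The offline gazetteer backend resolves a query by match class — exact
primary name, then exact alternate name, then all-query-tokens contained in
the primary name — breaking ties by population descending (the standard
population heuristic for toponym disambiguation) and finally by record id,
which makes results total-ordered and platform-independent. Qualified
queries (`X, Y`) match `X` as the name and require every qualifier to appear
in the record's administrative containment path or country code. Results
carry the fully qualified name, a granularity label (point_of_interest,
locality, administrative_area, country), and point coordinates; lookups are
cached per (backend, query) within a run. Remote services would plug in
through the same backend contract, but the bundled backend is the default so
nothing in the package ever requires a network. Cross-location
disambiguation (e.g. minimizing pairwise distance among an article's
locations) is deliberately absent: strings are geocoded independently.

## Evaluation

Extraction correctness against ground truth uses normalized case-insensitive
containment/equality between truth and extracted strings — a reproducible
surrogate for the manual judgment such evaluations normally rely on, with
explicit per-string judgments accepted as an override. Geocode correctness
is record-id equality when the truth carries a gazetteer id; otherwise a
great-circle distance tolerance of 25 km for locality/point-of-interest
results and 200 km for administrative areas (scales chosen to match the
spatial extent of each granularity), and name equality for countries.

Article-unit precision excludes articles with no extractions from the
precision mean, and articles with no truth locations from the recall mean:
scoring silence as either 0 or 1 would reward or punish abstention
arbitrarily. Full-pipeline precision counts a wrongly extracted string with
no geocode result as a true negative (outside the denominator), so it can
legitimately exceed extraction precision on some inputs. Error percentages
are rounded to one decimal; with seven categories their sum can drift from
100 by up to 0.35.

## Synthetic corpora

The fixture generator emulates the structure the pipeline exploits, at study
conditions fixed once: articles with a title, an untargeted introduction and
results section, one targeted section ("Materials and methods" /
"Patients and samples"), and a references section; 1–3 planted relevant
locations per article, each appearing verbatim in exactly one targeted
sentence; 0–2 distractors per article (company parentheticals that always
contain a discard word, and person-year citations); 0–1 background location
mentions in the introduction (relevant-looking places that only the
*no-extract* variant can reach, giving that ablation a measurable cost). The
ecology template puts a locality in every title; the biomedical template
plants hospitals and includes a quality mix with articles reporting no
location at all. All names — six countries, twelve admin areas, thirty-two
localities, six hospitals — are invented, and the generated gazetteer is the
single source of geographic truth, so geocoding of planted strings is exact
by construction. A single seeded generator governs all randomness; no global
random state is touched.

What passing tests on these fixtures shows: the pipeline's stages compose
correctly, the filter removes exactly the planted irrelevant mentions, the
ablations degrade in the expected directions, and every output is
deterministic. What they do not show: robustness to real NER noise, garbled
PDF text, non-blank-line paragraph layouts, vague or compositional place
descriptions, or gazetteer ambiguity at world scale — the fixture
vocabulary is unambiguous by design, so measured accuracies on synthetic
corpora are upper bounds, not estimates, of real-corpus performance.

## Problem sizes and numerical choices

The acceptance script uses 20-article corpora per condition, large enough to
exercise every template branch while completing in seconds. Reported ratios
are exact rational arithmetic in floating point (no iterative numerics);
reporting rounds to 3 decimals for ratios and 1 decimal for percentages.
Degenerate inputs are handled explicitly: empty documents raise typed
errors, empty extractions yield not-applicable metrics rather than zeros,
an empty failure list yields zero percentages, and harmonic F1 is defined as
0 at P = R = 0.

## Known limitations

- Heading pattern lists are reconstructions of what such corpora need, not
  learned from data; new domains will need profile edits.
- The plain-text heading heuristic can misfire on short period-less
  paragraphs; XML, when available, always wins.
- The lexicon tagger cannot recognize places absent from its table; real
  deployments should adapt a pretrained NER model through the tagger
  contract.
- Points are the only geometry; bounding boxes pass through when a backend
  supplies them, but no polygon support exists.
- Acknowledgements sections, coordinate strings, and compositional
  descriptions are not mined; the retained sentence context is the intended
  recovery path for a human annotator.
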