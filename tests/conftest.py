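import pytest

from scigeo.location_identification import (
    OTHER,
    LexiconTagger,
    Sentence,
    Token,
    join_tokens,
)
from scigeo.section_targeting import cancer_profile, orchards_profile


@pytest.fixture
def orchards():
    return orchards_profile()


@pytest.fixture
def cancer():
    return cancer_profile()


def make_sentence(tagged_tokens, article_id="art", heading="Methods"):
    """Build a Sentence from (surface, ner_tag) pairs for unit tests."""
    tokens = [
        Token(surface=s, normalized=s, pos_tag="NNP" if s[:1].isupper() else "NN", ner_tag=t)
        for s, t in tagged_tokens
    ]
    return Sentence(
        tokens=tokens,
        raw_text=join_tokens([s for s, _ in tagged_tokens]),
        article_id=article_id,
        heading=heading,
    )


def toks(spec_string):
    """Parse 'Nancy/LOC ( East of France/LOC )' into (surface, tag) pairs."""
    short = {"LOC": "LOCATION", "PER": "PERSON", "ORG": "ORGANIZATION"}
    out = []
    for item in spec_string.split():
        if "/" in item:
            surface, tag = item.rsplit("/", 1)
            out.append((surface, short.get(tag, tag)))
        else:
            out.append((item, OTHER))
    return out


@pytest.fixture
def simple_tagger():
    return LexiconTagger(
        {
            "Nancy": "LOCATION",
            "France": "LOCATION",
            "Florence": "LOCATION",
            "Italy": "LOCATION",
            "Madison": "LOCATION",
            "Boston": "LOCATION",
            "Massachusetts General Hospital": "ORGANIZATION",
            "University of Helsinki": "ORGANIZATION",
            "Carl Zeiss GmbH": "ORGANIZATION",
            "Jena": "LOCATION",
            "Germany": "LOCATION",
            "Smith": "PERSON",
        }
    )
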