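"""Normalization, sentence segmentation, tagging, and candidate assembly."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sentence, toks
from scigeo.errors import StageError
from scigeo.location_identification import (
    LOCATION,
    OTHER,
    LexiconTagger,
    assemble_candidates,
    normalize_text,
    segment_and_tag,
    span_is_valid,
    split_sentences,
    tokenize,
)


class TestNormalizeText:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Zürich", "Zurich"),
            ("São  Paulo", "Sao Paulo"),
            ("Besançon", "Besancon"),
            ("plain ascii", "plain ascii"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_text(raw) == expected

    @given(st.text(max_size=80))
    @settings(max_examples=300, deadline=None)
    def test_idempotent(self, s):
        once = normalize_text(s)
        assert normalize_text(once) == once


class TestSentenceSplitting:
    def test_two_sentences(self):
        out = split_sentences("Sites were near Nancy. Trees were sampled.")
        assert out == ["Sites were near Nancy.", "Trees were sampled."]

    @pytest.mark.parametrize("abbrev", ["Fig.", "et al.", "e.g.", "approx.", "ca."])
    def test_abbreviations_do_not_split(self, abbrev):
        text = f"Details in {abbrev} 2 are shown. Next sentence."
        assert len(split_sentences(text)) == 2

    def test_short_parenthetical_not_split(self):
        text = "Sites near Florence, Italy (43.77 N, 11.26 E) were used. Next one."
        out = split_sentences(text)
        assert len(out) == 2
        assert "(43.77 N, 11.26 E)" in out[0]


class TestLexiconTagger:
    def test_single_word(self):
        tagger = LexiconTagger({"Nancy": "LOCATION"})
        assert tagger.tag(["in", "Nancy", "today"]) == [OTHER, LOCATION, OTHER]

    def test_longest_match_wins(self):
        tagger = LexiconTagger(
            {"Massachusetts": "LOCATION", "Massachusetts General Hospital": "ORGANIZATION"}
        )
        tags = tagger.tag(["Massachusetts", "General", "Hospital"])
        assert tags == ["ORGANIZATION"] * 3

    def test_deterministic(self):
        tagger = LexiconTagger({"Nancy": "LOCATION", "Smith": "PERSON"})
        surfaces = ["Nancy", "met", "Smith"]
        assert tagger.tag(surfaces) == tagger.tag(surfaces)

    def test_diacritics_normalized(self):
        tagger = LexiconTagger({"Zurich": "LOCATION"})
        assert tagger.tag(["Zürich"]) == [LOCATION]

    def test_invalid_tag_rejected(self):
        with pytest.raises(ValueError):
            LexiconTagger({"x": "PLACE"})

    def test_from_tsv(self, tmp_path):
        path = tmp_path / "lexicon.tsv"
        path.write_text("# phrase\ttag\nNancy\tLOCATION\nSaint Elm Clinic\tORGANIZATION\n")
        tagger = LexiconTagger.from_tsv(path)
        assert tagger.tag(["Nancy"]) == [LOCATION]
        assert tagger.tag(["Saint", "Elm", "Clinic"]) == ["ORGANIZATION"] * 3


class TestSegmentAndTag:
    def test_sentences_carry_provenance(self, simple_tagger):
        sents = segment_and_tag(
            "Sites were near Nancy. Trees were sampled.",
            simple_tagger, article_id="a1", heading="Methods", paragraph_index=3,
        )
        assert len(sents) == 2
        assert sents[0].provenance == ("a1", "Methods", 3, 0)
        assert sents[1].provenance == ("a1", "Methods", 3, 1)
        nancy = [t for t in sents[0].tokens if t.surface == "Nancy"]
        assert nancy[0].ner_tag == LOCATION

    def test_tagger_failure_raises_stage_error_with_provenance(self):
        class Broken:
            def tag(self, surfaces):
                raise RuntimeError("boom")

        with pytest.raises(StageError) as err:
            segment_and_tag("Some text here.", Broken(), article_id="a9")
        assert err.value.provenance[0] == "a9"


class TestAssembleCandidates:
    def test_bridged_parenthetical(self, orchards):
        sent = make_sentence(toks("Sites in Nancy/LOC ( East of France/LOC )"))
        cands = assemble_candidates(sent, orchards)
        assert [c.candidate_string for c in cands] == ["Nancy (East of France)"]

    def test_no_entities_no_candidates(self, orchards):
        sent = make_sentence(toks("Trees were sampled in spring"))
        assert assemble_candidates(sent, orchards) == []

    def test_state_abbreviation_bridged(self, orchards):
        sent = make_sentence(toks("at Madison/LOC , WI last year"))
        cands = assemble_candidates(sent, orchards)
        assert [c.candidate_string for c in cands] == ["Madison, WI"]

    def test_all_org_span_kept_whole(self, orchards):
        sent = make_sentence(toks("at Massachusetts/ORG General/ORG Hospital/ORG today"))
        cands = assemble_candidates(sent, orchards)
        assert [c.candidate_string for c in cands] == ["Massachusetts General Hospital"]

    def test_every_candidate_has_entity(self, orchards):
        sent = make_sentence(
            toks("Plots near Nancy/LOC and also near Florence/LOC , Italy/LOC were used")
        )
        for cand in assemble_candidates(sent, orchards):
            assert any(t != OTHER for t in cand.tag_sequence)

    def test_candidates_ordered_and_disjoint(self, orchards):
        sent = make_sentence(
            toks("Nancy/LOC was sampled first then Florence/LOC , Italy/LOC later")
        )
        cands = assemble_candidates(sent, orchards)
        spans = [c.span for c in cands]
        assert spans == sorted(spans)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b <= c

    def test_cardinal_direction_absorbed_at_edge(self, orchards):
        sent = make_sentence(toks("sites across southern France/LOC were chosen"))
        cands = assemble_candidates(sent, orchards)
        assert [c.candidate_string for c in cands] == ["southern France"]

    def test_extension_words_empty_for_cancer_profile(self, cancer):
        sent = make_sentence(toks("sites across southern France/LOC were chosen"))
        cands = assemble_candidates(sent, cancer)
        assert [c.candidate_string for c in cands] == ["France"]

    def test_bridging_monotone_in_connector_set(self, orchards):
        # removing a connector word never produces fewer candidates
        sent = make_sentence(toks("Nancy/LOC in the east of France/LOC"))
        import dataclasses

        narrowed = dataclasses.replace(
            orchards, connector_words=orchards.connector_words - {"of", "the", "in"}
        )
        n_full = len(assemble_candidates(sent, orchards))
        n_narrow = len(assemble_candidates(sent, narrowed))
        assert n_narrow >= n_full


# --- brute-force oracle -----------------------------------------------------


def brute_force_candidates(sentence, profile):
    """Independent enumeration of maximal valid spans: try all O(n^2) spans,
    keep valid ones, drop spans contained in a larger valid span."""
    n = len(sentence.tokens)
    valid = [
        (s, e)
        for s in range(n)
        for e in range(s + 1, n + 1)
        if span_is_valid(sentence.tokens, s, e, profile)
    ]
    maximal = [
        (s, e)
        for (s, e) in valid
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for (s2, e2) in valid)
    ]
    return sorted(maximal)


VOCAB = [
    ("Nancy", "LOCATION"), ("France", "LOCATION"), ("Lyon", "LOCATION"),
    ("Smith", "PERSON"), ("Acme", "ORGANIZATION"),
    ("in", "OTHER"), ("of", "OTHER"), ("near", "OTHER"), ("the", "OTHER"),
    ("southern", "OTHER"), ("region", "OTHER"), (",", "OTHER"), ("(", "OTHER"),
    (")", "OTHER"), ("WI", "OTHER"), ("trees", "OTHER"), ("sampled", "OTHER"),
    ("1998", "OTHER"),
]


def test_assembly_agrees_with_brute_force_on_short_sentences(orchards):
    rng = random.Random(20240901)
    for _ in range(300):
        length = rng.randint(1, 12)
        tagged = [VOCAB[rng.randrange(len(VOCAB))] for _ in range(length)]
        sent = make_sentence(tagged)
        greedy = sorted(c.span for c in assemble_candidates(sent, orchards))
        brute = brute_force_candidates(sent, orchards)
        assert greedy == brute, f"disagreement on {[s for s, _ in tagged]}"
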