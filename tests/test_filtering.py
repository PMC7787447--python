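"""Candidate filtering, string cleaning, and deduplication."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sentence, toks
from scigeo.location_filtering import (
    ContentLocation,
    clean_location_string,
    deduplicate_locations,
    filter_candidates,
    split_comma_separated_countries,
)
from scigeo.location_identification import assemble_candidates


def candidates_from(spec_string, profile):
    return assemble_candidates(make_sentence(toks(spec_string)), profile)


class TestFilterCandidates:
    def test_discard_word_rejects_company(self, orchards):
        cands = candidates_from(
            "supplied by Carl/ORG Zeiss/ORG GmbH/ORG , Jena/LOC , Germany/LOC", orchards
        )
        out = filter_candidates(cands, orchards, mode="full")
        assert len(out) == 1
        assert out[0].rejected and out[0].rejection_reason == "discard_word"

    def test_keep_word_overrides_tag_rule(self, orchards):
        cands = candidates_from("at University/ORG of Helsinki/ORG today", orchards)
        out = filter_candidates(cands, orchards, mode="full")
        assert len(out) == 1
        assert not out[0].rejected
        assert out[0].location_string == "University of Helsinki"

    def test_keep_word_overrides_discard_word(self, orchards):
        # keep beats discard: archetypal relevant institutions are never dropped
        cands = candidates_from("at University/ORG Hospital/ORG Inc/ORG", orchards)
        out = filter_candidates(cands, orchards, mode="full")
        assert not out[0].rejected

    def test_person_only_span_rejected(self, orchards):
        cands = candidates_from("described by Smith/PER previously", orchards)
        out = filter_candidates(cands, orchards, mode="full")
        assert out[0].rejected and out[0].rejection_reason == "no_location_tag"

    def test_person_year_citation_rule(self, orchards):
        cands = candidates_from("as in Smith/PER 1998 , Boston/LOC", orchards)
        person_spans = [o for o in filter_candidates(cands, orchards, mode="full")
                        if o.location_string.startswith("Smith")]
        assert person_spans and person_spans[0].rejection_reason in (
            "tag_word_combination", "no_location_tag"
        )

    def test_no_filter_passes_everything(self, orchards):
        spec = "supplied by Carl/ORG Zeiss/ORG GmbH/ORG , Jena/LOC and Smith/PER too"
        cands = candidates_from(spec, orchards)
        out = filter_candidates(cands, orchards, mode="no_filter")
        assert len(out) == len(cands)
        assert all(not o.rejected for o in out)

    def test_locations_only_truncates_to_location_tokens(self, orchards):
        cands = candidates_from(
            "at Massachusetts/ORG General/ORG Hospital/ORG , Boston/LOC , USA/LOC", orchards
        )
        out = filter_candidates(cands, orchards, mode="locations_only")
        kept = [o for o in out if not o.rejected]
        assert kept and kept[0].location_string == "Boston, USA"

    def test_locations_only_rejects_entity_spans_without_locations(self, orchards):
        cands = candidates_from("by Smith/PER previously", orchards)
        out = filter_candidates(cands, orchards, mode="locations_only")
        assert out[0].rejected

    def test_full_kept_subset_of_no_filter(self, orchards):
        spec = (
            "sites at Nancy/LOC ( East of France/LOC ) supplied by Acme/ORG Inc/ORG , "
            "Jena/LOC noted by Smith/PER 1998"
        )
        cands = candidates_from(spec, orchards)
        full_kept = {o.location_string for o in filter_candidates(cands, orchards, "full")
                     if not o.rejected}
        nf_kept = {o.location_string for o in filter_candidates(cands, orchards, "no_filter")
                   if not o.rejected}
        assert full_kept <= nf_kept

    def test_rejections_carry_reason(self, orchards):
        spec = "by Acme/ORG Inc/ORG and Smith/PER too"
        for out in filter_candidates(candidates_from(spec, orchards), orchards, "full"):
            if out.rejected:
                assert out.rejection_reason is not None


class TestCleanLocationString:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Florence, Italy,", "Florence, Italy"),
            ("Bern in", "Bern"),
            ("Nancy (East of France)", "Nancy (East of France)"),
            ("Madrid, ", "Madrid"),
            ("Lyon (", "Lyon"),
            ("Oslo in the", "Oslo"),
            ("Turin.", "Turin"),
        ],
    )
    def test_examples(self, raw, expected):
        assert clean_location_string(raw) == expected

    @given(st.text(alphabet=" abcdeABCDE(),.inof", max_size=40))
    @settings(max_examples=300, deadline=None)
    def test_idempotent_and_never_longer(self, s):
        once = clean_location_string(s)
        assert clean_location_string(once) == once
        assert len(once) <= len(s)


class TestSplitCountryLists:
    countries = frozenset({"France", "Spain", "Italy"})

    def _loc(self, s):
        return ContentLocation(
            location_string=s, sentence=make_sentence([("x", "OTHER")]), article_id="a"
        )

    def test_all_country_comma_group_split(self):
        out = split_comma_separated_countries([self._loc("France, Spain, Italy")],
                                              self.countries)
        assert [o.location_string for o in out] == ["France", "Spain", "Italy"]

    def test_qualified_string_not_split(self):
        # "Paris, France" is a qualified locality, not a country list
        out = split_comma_separated_countries([self._loc("Paris, France")], self.countries)
        assert [o.location_string for o in out] == ["Paris, France"]

    def test_single_country_untouched(self):
        out = split_comma_separated_countries([self._loc("France")], self.countries)
        assert [o.location_string for o in out] == ["France"]


class TestDeduplicate:
    def _loc(self, s, article="a"):
        sent = make_sentence([("x", "OTHER")])
        return ContentLocation(location_string=s, sentence=sent, article_id=article)

    def test_case_fold_duplicate_keeps_first(self):
        out = deduplicate_locations([self._loc("Seville, Spain"), self._loc("seville, Spain")])
        assert [o.location_string for o in out] == ["Seville, Spain"]

    def test_distinct_strings_both_kept(self):
        out = deduplicate_locations([self._loc("Seville"), self._loc("Seville, Spain")])
        assert len(out) == 2

    def test_duplicate_count_recorded(self):
        out = deduplicate_locations([self._loc("Rome"), self._loc("Rome"), self._loc("rome")])
        assert len(out) == 1
        assert out[0].duplicate_count == 2
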