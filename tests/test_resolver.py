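import random

import edlib
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sectionid.resolver import (
    RawSection,
    ResolveOptions,
    Span,
    find_exact,
    find_fuzzy,
    levenshtein,
    parse_output,
    resolve_sections,
    resolve_with_stats,
    similarity,
)

from oracles import levenshtein_recursive


class TestParseOutput:
    def test_single_block(self):
        raws = parse_output(
            "Section 1: Allergies\nStarts at: ALLERGIES:\nEnds at: to penicillin."
        )
        assert raws == [RawSection(1, "Allergies", "ALLERGIES:", "to penicillin.")]

    def test_empty(self):
        assert parse_output("") == []

    def test_two_blocks_with_garbage_between(self):
        raw = (
            "Here are the sections I found:\n"
            "Section 1: A\nStarts at: x1\nEnds at: y1\n"
            "some interleaved commentary\n"
            "Section 2: B\nStarts at: x2\nEnds at: y2\nDone!"
        )
        raws = parse_output(raw)
        assert [r.index for r in raws] == [1, 2]
        assert raws[0].start_text == "x1"
        # trailing garbage folds into the last free-text field
        assert raws[1].end_text.startswith("y2")

    def test_fields_are_trimmed(self):
        raws = parse_output("Section 3:  Name \nStarts at:  s \nEnds at:  e ")
        assert raws == [RawSection(3, "Name", "s", "e")]


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("abc", "abc", 0), ("kitten", "sitting", 3), ("", "abc", 3), ("abc", "", 3)],
    )
    def test_known_values(self, a, b, expected):
        assert levenshtein(a, b) == expected

    @given(st.text(alphabet="abcd", max_size=8), st.text(alphabet="abcd", max_size=8))
    @settings(derandomize=True, max_examples=60)
    def test_matches_recursive_oracle(self, a, b):
        assert levenshtein(a, b) == levenshtein_recursive(a, b)

    @given(st.text(max_size=30), st.text(max_size=30))
    @settings(derandomize=True, max_examples=80)
    def test_matches_edlib(self, a, b):
        expected = edlib.align(a, b, task="distance")["editDistance"] if a and b else max(len(a), len(b))
        assert levenshtein(a, b) == expected


class TestSimilarity:
    def test_identical_is_100(self):
        assert similarity("Hospital course", "Hospital course") == 100.0

    def test_one_edit_fourteen_chars(self):
        assert similarity("Admission Date", "Admision Date") == pytest.approx(100 * 13 / 14)

    def test_kitten_sitting(self):
        assert similarity("kitten", "sitting") == pytest.approx(100 * 4 / 7)

    def test_both_empty_defined_as_100(self):
        assert similarity("", "") == 100.0

    def test_boundary_is_exact_ninety(self):
        # one deletion against a length-10 query must score exactly 90.0
        assert similarity("ALLERGIES:", "ALLERGIE:") == 90.0


class TestFindExact:
    def test_leftmost_from_zero(self):
        assert find_exact("AB AB", "AB", 0) == Span(0, 1)

    def test_respects_from_pos(self):
        assert find_exact("AB AB", "AB", 1) == Span(3, 4)

    def test_absent(self):
        assert find_exact("AB AB", "ZZ", 0) is None

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            find_exact("note", "", 0)


class TestFindFuzzy:
    def test_exact_occurrence_scores_100(self):
        hit = find_fuzzy("xx HOSPITAL COURSE yy", "HOSPITAL COURSE", 0, 90)
        assert hit == (Span(3, 17), 100.0)

    def test_boundary_90_accepted(self):
        # query length 10, note contains a 1-deletion variant: score exactly 90
        hit = find_fuzzy("see ALLERGIE: list", "ALLERGIES:", 0, 90.0)
        assert hit is not None
        span, score = hit
        assert score == 90.0
        assert span.start == 4

    def test_below_threshold_rejected(self):
        # best candidate is a 1-deletion variant of a length-9 query: 800/9 < 90
        assert find_fuzzy("see ALLERGE: list", "ALLERGES:", 0, 90.0) is None

    def test_respects_from_pos(self):
        hit = find_fuzzy("AB AB", "AB", 1, 90)
        assert hit == (Span(3, 4), 100.0)

    def test_threshold_100_equals_exact(self):
        rng = random.Random(1)
        for _ in range(25):
            note = "".join(rng.choice("abc ") for _ in range(60))
            query = "".join(rng.choice("abc ") for _ in range(4))
            exact = find_exact(note, query, 0)
            fuzzy = find_fuzzy(note, query, 0, threshold=100.0)
            if exact is None:
                assert fuzzy is None
            else:
                assert fuzzy == (exact, 100.0)


def _schema_for(labels):
    from sectionid.schema import SectionSchema, SectionType

    return SectionSchema(types=tuple(SectionType(l, "def") for l in labels))


class TestResolveSections:
    NOTE = "ALLERGIES:\npenicillin rash noted.SOCIAL HISTORY:\ndenies tobacco use."

    def _raws(self):
        return [
            RawSection(1, "Allergies", "ALLERGIES:", "rash noted."),
            RawSection(2, "Social history", "SOCIAL HISTORY:", "tobacco use."),
        ]

    def test_round_trip_two_sections(self, tiny_schema):
        sections = resolve_sections(self.NOTE, self._raws(), tiny_schema)
        assert [s.label for s in sections] == ["Allergies", "Social history"]
        assert sections[0].span == Span(0, 32)
        assert sections[1].span == Span(33, len(self.NOTE) - 1)

    def test_invalid_name_dropped_when_case_sensitive(self, tiny_schema):
        raws = [RawSection(1, "allergies", "ALLERGIES:", "rash noted.")]
        assert resolve_sections(self.NOTE, raws, tiny_schema) == []

    def test_case_insensitive_resolves_canonical_casing(self, tiny_schema):
        raws = [RawSection(1, "ALLERGIES", "ALLERGIES:", "rash noted.")]
        opts = ResolveOptions(case_insensitive_names=True)
        sections = resolve_sections(self.NOTE, raws, tiny_schema, opts)
        assert sections[0].label == "Allergies"

    def test_bad_end_text_keeps_tentative_end(self, tiny_schema):
        raws = [
            RawSection(1, "Allergies", "ALLERGIES:", "zz completely wrong zz"),
            RawSection(2, "Social history", "SOCIAL HISTORY:", "tobacco use."),
        ]
        sections, stats = resolve_with_stats(self.NOTE, raws, tiny_schema)
        assert sections[0].span == Span(0, 32)  # tentative end: next start - 1
        assert stats.end_text_fallback == 1

    def test_unfindable_start_dropped(self, tiny_schema):
        raws = [RawSection(1, "Allergies", "NO SUCH ANCHOR", "rash noted.")]
        sections, stats = resolve_with_stats(self.NOTE, raws, tiny_schema)
        assert sections == []
        assert stats.dropped_start_not_found == 1

    def test_duplicate_start_offsets_deduplicated(self, tiny_schema):
        raws = [
            RawSection(1, "Allergies", "ALLERGIES:", "rash noted."),
            RawSection(2, "Social history", "ALLERGIES:", "rash noted."),
        ]
        # second start search resumes past the cursor, fails, retries from 0
        # and lands on the same offset -> deduplicated
        sections, stats = resolve_with_stats(self.NOTE, raws, tiny_schema)
        assert len(sections) == 1
        assert stats.dropped_duplicate_start == 1

    def test_emission_order_cursor_disambiguates_repeats(self):
        schema = _schema_for(["A", "B"])
        note = "anchor one body.anchor two body."
        raws = [
            RawSection(1, "A", "anchor", "body."),
            RawSection(2, "B", "anchor", "body."),
        ]
        sections = resolve_sections(note, raws, schema)
        assert [s.span.start for s in sections] == [0, 16]

    def test_end_uses_rightmost_match_in_window(self):
        schema = _schema_for(["A"])
        note = "begin end middle end tail"
        raws = [RawSection(1, "A", "begin", "end")]
        sections = resolve_sections(note, raws, schema)
        # two occurrences of "end"; the rightmost within the span wins
        assert sections[0].span == Span(0, 19)

    def test_worst_case_yields_empty_list(self, tiny_schema):
        assert resolve_sections("note", [], tiny_schema) == []

    @pytest.mark.parametrize("fuzzy", [False, True])
    def test_output_spans_sorted_disjoint_in_bounds(self, fuzzy):
        rng = random.Random(7)
        labels = ["A", "B", "C", "D"]
        schema = _schema_for(labels)
        for _ in range(20):
            note = "".join(rng.choice("abcde .\n") for _ in range(rng.randint(30, 120)))
            raws = []
            for i in range(rng.randint(1, 6)):
                s = rng.randint(0, len(note) - 6)
                raws.append(
                    RawSection(
                        i,
                        rng.choice(labels + ["Nope"]),
                        note[s : s + rng.randint(3, 6)].strip() or "x",
                        note[s : s + 3].strip() or "y",
                    )
                )
            opts = ResolveOptions(fuzzy_spans=fuzzy)
            sections = resolve_sections(note, raws, schema, opts)
            starts = [sec.span.start for sec in sections]
            assert starts == sorted(starts)
            for a, b in zip(sections, sections[1:]):
                assert a.span.end < b.span.start
            for sec in sections:
                assert 0 <= sec.span.start <= sec.span.end < len(note)

    def test_raising_threshold_never_adds_sections(self, tiny_schema):
        raws = [
            RawSection(1, "Allergies", "ALLERGIS:", "rash notd."),  # 1 edit each
            RawSection(2, "Social history", "SOCIAL HISTRY:", "tobacco use."),
        ]
        counts = []
        for threshold in (80.0, 90.0, 95.0, 100.0):
            opts = ResolveOptions(fuzzy_spans=True, fuzzy_threshold=threshold)
            counts.append(len(resolve_sections(self.NOTE, raws, tiny_schema, opts)))
        assert counts == sorted(counts, reverse=True)


class TestSpanType:
    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            Span(3, 2)

    def test_length_is_inclusive(self):
        assert len(Span(2, 4)) == 3


def test_raw_section_requires_nonempty_fields():
    with pytest.raises(ValueError):
        RawSection(1, " ", "x", "y")


def test_scan_handles_unicode():
    note = "café au lait — histoire présente"
    hit = find_fuzzy(note, "histoire presente", 0, 80)
    assert hit is not None
    assert np.isclose(hit[1], 100 * 16 / 17)
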