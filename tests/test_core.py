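"""Domain types: fixed-width encoding, combination keys, parsing, aggregates."""

import io
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxchain import (
    AggregateResult,
    FieldOverflowError,
    Observation,
    Outcome,
    ParseError,
    QueryTriple,
    decode_fixed32,
    encode_fixed32,
    make_combination_key,
    parse_observation,
    read_observations_csv,
    write_observations_csv,
)
from pgxchain.core import canonical_variant


class TestFixed32:
    def test_pads_right_with_zero_bytes(self):
        raw = encode_fixed32("CYP3A5")
        assert len(raw) == 32
        assert raw[:6] == b"CYP3A5"
        assert raw[6:] == bytes(26)

    def test_empty_string_is_all_zero(self):
        assert encode_fixed32("") == bytes(32)
        assert decode_fixed32(bytes(32)) == ""

    def test_overflow_names_field(self):
        with pytest.raises(FieldOverflowError) as exc:
            encode_fixed32("x" * 33, field="gene")
        assert exc.value.field == "gene"

    def test_multibyte_characters_count_in_bytes(self):
        # 17 two-byte characters = 34 bytes > 32, though only 17 characters.
        with pytest.raises(FieldOverflowError):
            encode_fixed32("é" * 17)

    @settings(derandomize=True, max_examples=200)
    @given(st.text(max_size=32).filter(lambda s: len(s.encode()) <= 32))
    def test_roundtrip_identity(self, text):
        # Trailing NULs cannot survive zero-padding; exclude them, as storage
        # never produces them.
        text = text.rstrip("\x00")
        assert decode_fixed32(encode_fixed32(text)) == text


class TestCombinationKey:
    def test_deterministic_on_repeat_calls(self):
        a = make_combination_key("CYP3A5", 52, "pegloticase")
        b = make_combination_key("CYP3A5", 52, "pegloticase")
        assert a == b
        assert a.storage_key() == b.storage_key()

    def test_adversarial_separators_do_not_collide(self):
        a = make_combination_key("A", 1, "B|2|C")
        b = make_combination_key("A|1|B", 2, "C")
        assert a.storage_key() != b.storage_key()

    def test_variant_is_canonical_decimal(self):
        assert make_combination_key("G", 52, "d").variant == "52"

    def test_grid_enumeration_yields_distinct_keys(self):
        # Brute-force: a 3x3x3 grid of values must give 27 distinct keys.
        keys = {
            make_combination_key(g, v, d).storage_key()
            for g, v, d in itertools.product(
                ["G1", "G2", "G3"], [1, 2, 3], ["d1", "d2", "d3"]
            )
        }
        assert len(keys) == 27

    def test_injectivity_over_random_triples(self):
        # 10^4 random triples, drug names salted with separator-like
        # characters; the length-prefixed key must stay injective.
        import random

        rng = random.Random(0)
        alphabet = "AB|:123"
        triples = set()
        while len(triples) < 10_000:
            triples.add(
                (
                    "".join(rng.choices(alphabet, k=rng.randint(1, 6))),
                    rng.randint(0, 99),
                    "".join(rng.choices(alphabet, k=rng.randint(1, 8))),
                )
            )
        keys = {make_combination_key(g, v, d).storage_key() for g, v, d in triples}
        assert len(keys) == len(triples)


class TestObservation:
    def test_negative_variant_rejected(self):
        with pytest.raises(ValueError):
            Observation("G", -3, "d", Outcome.IMPROVED, True, True)

    def test_empty_drug_rejected(self):
        with pytest.raises(ValueError):
            Observation("G", 1, "  ", Outcome.IMPROVED, False, False)

    def test_long_gene_rejected_long_drug_allowed(self):
        with pytest.raises(FieldOverflowError):
            Observation("G" * 33, 1, "d", Outcome.IMPROVED, False, False)
        obs = Observation("G", 1, "x" * 200, Outcome.IMPROVED, False, False)
        assert len(obs.drug) == 200

    def test_whitespace_stripped(self):
        obs = Observation("  CYP3A5 ", 52, " pegloticase ", Outcome.UNCHANGED, True, True)
        assert (obs.gene, obs.drug) == ("CYP3A5", "pegloticase")

    def test_canonical_variant_rejects_bool_and_float(self):
        with pytest.raises(TypeError):
            canonical_variant(True)
        with pytest.raises(TypeError):
            canonical_variant(1.5)


class TestQueryTriple:
    @pytest.mark.parametrize(
        "triple, n_ands, full",
        [
            (QueryTriple(), None, True),
            (QueryTriple(gene="CYP3A5"), 0, False),
            (QueryTriple(gene="CYP3A5", variant=52), 1, False),
            (QueryTriple(gene="CYP3A5", variant=52, drug="pegloticase"), 2, False),
        ],
    )
    def test_n_ands_counts_specified_fields(self, triple, n_ands, full):
        assert triple.n_ands == n_ands
        assert triple.is_full_wildcard is full

    def test_variant_key_is_canonical(self):
        assert QueryTriple(variant=7).variant_key == "7"
        assert QueryTriple(variant="7").variant_key == "7"


class TestParseObservation:
    def test_worked_example_row(self, example_observation):
        obs = parse_observation("CYP3A5,52,pegloticase,UNCHANGED,true,true")
        assert obs == example_observation

    def test_lowercase_outcome_and_numeric_booleans(self):
        obs = parse_observation("G1,0,d,improved,0,0")
        assert obs.outcome is Outcome.IMPROVED
        assert not obs.suspected_relation and not obs.serious_side_effect

    @pytest.mark.parametrize(
        "row, column",
        [
            ("G1,-3,d,IMPROVED,true,true", "variant"),
            ("G1,x,d,IMPROVED,true,true", "variant"),
            ("G1,1,d,BETTER,true,true", "outcome"),
            ("G1,1,d,IMPROVED,maybe,true", "relation"),
            ("G1,1,d,IMPROVED,true,2", "sideEffect"),
        ],
    )
    def test_malformed_rows_name_row_and_column(self, row, column):
        with pytest.raises(ParseError) as exc:
            parse_observation(row, row_number=7)
        assert exc.value.row == 7
        assert exc.value.column == column

    def test_wrong_column_count(self):
        with pytest.raises(ParseError):
            parse_observation("G1,1,d,IMPROVED,true")


class TestCsvRoundTrip:
    def test_write_then_read_preserves_observations(self, example_observation):
        rows = [
            example_observation,
            Observation("G1", 0, "drug with, comma", Outcome.IMPROVED, False, True),
        ]
        buf = io.StringIO()
        write_observations_csv(buf, rows)
        buf.seek(0)
        assert buf.readline().strip() == "gene,variant,drug,outcome,relation,sideEffect"
        buf.seek(0)
        assert read_observations_csv(buf) == rows

    def test_bad_header_rejected(self):
        with pytest.raises(ParseError):
            read_observations_csv(io.StringIO("a,b,c,d,e,f\n"))


class TestAggregateResult:
    def test_percentages_follow_counts_and_sum_to_100(self):
        combo = make_combination_key("G", 1, "d")
        r = AggregateResult.from_counts(combo, 4, 0, 3, 2, 1, 1)
        assert (r.improved_pct, r.unchanged_pct, r.deteriorated_pct) == (50.0, 25.0, 25.0)
        assert r.suspected_pct == 75.0 and r.side_effect_pct == 0.0
        assert abs(r.improved_pct + r.deteriorated_pct + r.unchanged_pct - 100) < 1e-9

    def test_outcome_counts_must_sum_to_total(self):
        combo = make_combination_key("G", 1, "d")
        with pytest.raises(ValueError):
            AggregateResult.from_counts(combo, 4, 0, 0, 1, 1, 1)

    def test_zero_observation_aggregates_are_impossible(self):
        combo = make_combination_key("G", 1, "d")
        with pytest.raises(ValueError):
            AggregateResult.from_counts(combo, 0, 0, 0, 0, 0, 0)

    def test_json_dict_rounds_percentages_for_display(self):
        combo = make_combination_key("G", 1, "d")
        r = AggregateResult.from_counts(combo, 3, 1, 1, 1, 1, 1)
        d = r.to_json_dict()
        assert d["improved_pct"] == 33.33
        # full precision retained in the model
        assert r.improved_pct == 100.0 / 3.0
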