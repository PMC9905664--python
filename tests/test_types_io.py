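"""Domain types, delta-notation conversion, and the breath CSV contract."""
import textwrap

import numpy as np
import pytest
from hypothesis import given, strategies as st

import isowash as iw
from isowash.errors import (
    DuplicateSampleError,
    RowParseError,
    SchemaError,
    ValidationError,
)
from isowash.types import parse_sex, parse_species


class TestRatioToDelta:
    @pytest.mark.parametrize(
        "factor, expected",
        [(1.0, 0.0), (1.01, 10.0), (0.98874, -11.26)],
    )
    def test_known_values(self, factor, expected):
        pair = iw.RatioPair(r_sample=factor * 0.0112372, r_standard=0.0112372)
        assert iw.ratio_to_delta(pair) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValidationError):
            iw.RatioPair(r_sample=-1.0, r_standard=0.0112372)
        with pytest.raises(ValidationError):
            iw.RatioPair(r_sample=0.011, r_standard=0.0)

    @given(
        r1=st.floats(1e-6, 1e3, allow_nan=False),
        r2=st.floats(1e-6, 1e3, allow_nan=False),
        std=st.floats(1e-6, 1e3, allow_nan=False),
    )
    def test_strictly_increasing_and_zero_at_standard(self, r1, r2, std):
        d1 = iw.ratio_to_delta(iw.RatioPair(r1, std))
        d2 = iw.ratio_to_delta(iw.RatioPair(r2, std))
        if r1 < r2:
            assert d1 < d2
        assert iw.ratio_to_delta(iw.RatioPair(std, std)) == 0.0


class TestDomainTypes:
    def test_sample_invariants(self):
        with pytest.raises(ValidationError):
            iw.BreathSample(time_min=-1.0, d13c=-20.0)
        with pytest.raises(ValidationError):
            iw.BreathSample(time_min=0.0, d13c=float("nan"))
        with pytest.raises(ValidationError):
            iw.BreathSample(time_min=0.0, d13c=-20.0, co2_ppm=0.0)

    def test_series_requires_strictly_increasing_times(self):
        samples = [iw.BreathSample(3.0, -20.0), iw.BreathSample(3.0, -21.0)]
        with pytest.raises(ValidationError, match="strictly increasing"):
            iw.BirdSeries("b1", iw.Species.rufous, iw.Sex.female, 2010, "s", samples)

    def test_washout_params_require_positive_tau(self):
        with pytest.raises(ValidationError):
            iw.WashoutParams(d13c_0=-12.0, d13c_inf=-27.0, tau_min=0.0)

    def test_species_normalization(self):
        assert parse_species("Broad-Tailed") is iw.Species.broad_tailed
        assert parse_species("RUFOUS") is iw.Species.rufous
        with pytest.raises(ValidationError, match="unknown species"):
            parse_species("anna")

    def test_sex_tolerates_missing(self):
        assert parse_sex("F") is iw.Sex.female
        assert parse_sex("") is iw.Sex.unknown
        assert parse_sex("hatch-year") is iw.Sex.unknown


HEADER = "bird_id,species,sex,year,site,time_min,d13c\n"


class TestBreathTable:
    def test_single_bird_five_samples(self, tmp_path):
        body = "".join(
            f"b1,rufous,female,2010,wycolo,{t},{-12 - t}\n" for t in [0, 3, 6, 9, 12]
        )
        path = tmp_path / "one.csv"
        path.write_text(HEADER + body)
        coll = iw.read_breath_table(path)
        assert len(coll) == 1 and len(coll[0]) == 5
        assert coll[0].times == [0, 3, 6, 9, 12]

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(HEADER)
        assert iw.read_breath_table(path) == []

    def test_interleaved_birds_grouped_and_sorted(self, tmp_path):
        rows = []
        for t in [6, 0, 12, 3, 9]:
            rows.append(f"b2,rufous,f,2010,wycolo,{t},{-15 - 0.1 * t}\n")
            rows.append(f"b1,broad_tailed,m,2010,wycolo,{t},{-20 + 0.1 * t}\n")
        path = tmp_path / "two.csv"
        path.write_text(HEADER + "".join(rows))
        coll = iw.read_breath_table(path)
        assert [b.bird_id for b in coll] == ["b1", "b2"]
        for bird in coll:
            assert bird.times == sorted(bird.times) == [0, 3, 6, 9, 12]
        assert coll[0].species is iw.Species.broad_tailed

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("bird_id,species,sex,year,site,time_min\nb1,rufous,f,2010,s,0\n")
        with pytest.raises(SchemaError, match="d13c"):
            iw.read_breath_table(path)

    def test_duplicate_time_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(HEADER + "b1,rufous,f,2010,s,0,-20\nb1,rufous,f,2010,s,0,-21\n")
        with pytest.raises(DuplicateSampleError, match="b1"):
            iw.read_breath_table(path)

    def test_unparseable_numeric_reports_line(self, tmp_path):
        path = tmp_path / "junk.csv"
        path.write_text(HEADER + "b1,rufous,f,2010,s,0,-20\nb1,rufous,f,2010,s,3,oops\n")
        with pytest.raises(RowParseError, match="line 3") as exc_info:
            iw.read_breath_table(path)
        assert exc_info.value.line == 3

    def test_round_trip_identity(self, tmp_path):
        collection, _ = iw.simulate_population(iw.preset_2010(seed=1))
        path = tmp_path / "rt.csv"
        iw.write_breath_table(collection, path)
        back = iw.read_breath_table(path)
        assert len(back) == len(collection)
        original = {b.bird_id: b for b in collection}
        for bird in back:
            src = original[bird.bird_id]
            assert (bird.species, bird.sex, bird.year, bird.site) == (
                src.species,
                src.sex,
                src.year,
                src.site,
            )
            assert bird.times == src.times
            assert bird.d13c_values == src.d13c_values  # exact, full precision

    def test_write_empty_collection_is_header_only(self, tmp_path):
        path = tmp_path / "none.csv"
        iw.write_breath_table([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("bird_id,")

    def test_row_count_conservation(self, tmp_path):
        collection, _ = iw.simulate_population(
            iw.preset_2010(seed=2, n_birds=1, species=["rufous"])
        )
        path = tmp_path / "one.csv"
        iw.write_breath_table(collection, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + len(collection[0])
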