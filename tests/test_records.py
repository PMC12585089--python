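import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coastiso.errors import EmptyDatasetError, UnmappedVocabularyError
from coastiso.records import (
    DEFAULT_SECTORS,
    Dataset,
    assign_sector,
    assign_sectors,
    classify_feeding_habit,
    depth_filter,
    parse_records,
    synonymize_endmember,
    write_records,
)


class TestParse:
    def test_rows_missing_required_fields_are_excluded_and_counted(
        self, records_csv
    ):
        path = records_csv(
            [{}, {"date": "2011-01-01"}, {"date": "2012-01-01"},
             {"depth_m": np.nan}]
        )
        dataset, report = parse_records(path)
        assert len(dataset) == 3
        assert report.n_excluded == 1
        assert report.summary() == "1 excluded: missing depth_m"

    def test_julian_day_counts_from_earliest_collection_date(
        self, records_csv
    ):
        path = records_csv(
            [{"date": "1999-05-06"}, {"date": "2022-08-17"}]
        )
        dataset, _ = parse_records(path)
        assert sorted(dataset.frame["julian_day"]) == [0, 8504]
        assert str(dataset.origin_date) == "1999-05-06"

    def test_sanity_envelope_excludes_implausible_values(self, records_csv):
        path = records_csv([{}, {"d13C": -155.0}, {"d15N": 55.0}])
        dataset, report = parse_records(path)
        assert len(dataset) == 1
        rules = set(report.frame["rule_violated"])
        assert rules == {"d13C outside sanity envelope",
                         "d15N outside sanity envelope"}

    def test_all_rows_invalid_raises_empty_dataset(self, records_csv):
        path = records_csv([{"d13C": np.nan}])
        with pytest.raises(EmptyDatasetError):
            parse_records(path)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("date,lat\n2010-01-01,70\n")
        with pytest.raises(ValueError, match="required columns"):
            parse_records(p)

    def test_roundtrip_write_then_parse_is_identity(
        self, records_csv, tmp_path
    ):
        path = records_csv(
            [{"date": "2005-06-01", "d13C": -24.5},
             {"date": "2010-07-01", "d13C": -19.25, "genus": "Macoma"}]
        )
        ds1, _ = parse_records(path)
        out = tmp_path / "again.csv"
        write_records(ds1, out)
        ds2, report = parse_records(out)
        assert report.n_excluded == 0
        pd.testing.assert_frame_equal(
            ds1.frame, ds2.frame[ds1.frame.columns], check_dtype=False
        )


class TestSectors:
    @pytest.mark.parametrize(
        "lon,expected",
        [
            (-180.0, "Northern Bering/Chukchi Seas"),
            (-170.0, "Northern Bering/Chukchi Seas"),
            (-157.0, "Beaufort Sea"),  # western bound inclusive
            (-140.0, "Beaufort Sea"),
            (-123.0, "Canadian Arctic Archipelago"),
            (-100.0, "Canadian Arctic Archipelago"),
            (-78.0, "Baffin Bay"),
            (-60.0, "Baffin Bay"),
            (-45.0, "East Greenland"),
            (-20.0, "East Greenland"),
            (0.0, "Svalbard"),
            (15.0, "Svalbard"),
            (180.0, "Svalbard"),
        ],
    )
    def test_longitude_maps_to_sector(self, lon, expected):
        assert assign_sector(lon) == expected

    @pytest.mark.parametrize("lon", [-180.5, 181.0, np.nan])
    def test_out_of_domain_longitude_rejected(self, lon):
        with pytest.raises(ValueError):
            assign_sector(lon)

    @settings(max_examples=300, deadline=None)
    @given(st.floats(min_value=-180.0, max_value=180.0))
    def test_assignment_total_and_single_valued(self, lon):
        hits = [
            name
            for name, west, east in DEFAULT_SECTORS.intervals
            if west <= lon < east or (east == 180.0 and lon == 180.0)
        ]
        assert len(hits) == 1
        assert assign_sector(lon) == hits[0]


class TestDepthFilter:
    def _dataset(self, records_csv, rows):
        dataset, _ = parse_records(records_csv(rows))
        return assign_sectors(dataset)

    def test_deep_shallow_shelf_records_removed(self, records_csv):
        rows = [{"lon": -140.0, "depth_m": d} for d in
                (10, 20, 30, 40, 44, 45, 50, 60)]  # Beaufort
        rows += [{"lon": -165.0, "depth_m": 30.0},
                 {"lon": -165.0, "depth_m": 30.0}]
        ds = self._dataset(records_csv, rows)
        out, report = depth_filter(ds)
        assert len(ds) == 10 and len(out) == 8
        assert report.n_excluded == 2
        # "deeper than 45 m" is strict: exactly 45 m is retained
        assert (out.frame["depth_m"] <= 45).loc[
            out.frame["sector"] == "Beaufort Sea"].all()

    def test_deep_records_outside_named_sectors_untouched(
        self, records_csv
    ):
        rows = [{"lon": 15.0, "depth_m": 200.0},
                {"lon": -100.0, "depth_m": 500.0}]
        ds = self._dataset(records_csv, rows)
        out, report = depth_filter(ds)
        assert len(out) == 2 and report.n_excluded == 0

    def test_allow_list_retains_deep_shelf_site(self, records_csv):
        rows = [{"lon": -140.0, "depth_m": 60.0},
                {"lon": -140.0, "depth_m": 60.0}]
        ds = self._dataset(records_csv, rows)
        keep_id = ds.frame.index[0]
        out, report = depth_filter(ds, retained_sites=[keep_id])
        assert keep_id in out.frame.index
        assert len(out) == 1 and report.n_excluded == 1

    def test_output_is_subset_of_input(self, records_csv, rng):
        rows = [
            {"lon": float(rng.uniform(-180, 180)),
             "depth_m": float(rng.uniform(0, 100))}
            for _ in range(40)
        ]
        ds = self._dataset(records_csv, rows)
        out, _ = depth_filter(ds)
        assert set(out.frame.index) <= set(ds.frame.index)

    def test_requires_sectors(self, records_csv):
        ds, _ = parse_records(records_csv([{}]))
        with pytest.raises(ValueError, match="sector"):
            depth_filter(ds)


class TestVocabulary:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("grazer", "deposit_feeder"),
            ("surface deposit feeder", "deposit_feeder"),
            ("subsurface deposit feeder", "deposit_feeder"),
            ("filter feeder", "suspension_feeder"),
            ("suspension feeder", "suspension_feeder"),
            ("parasite", "predator"),
            ("fish", "predator"),
            ("mammal", "predator"),
            ("scavenger", "opportunist_scavenger"),
            ("omnivore", "opportunist_scavenger"),
            ("Omnivore ", "opportunist_scavenger"),  # case/space robust
        ],
    )
    def test_feeding_habit_aggregation(self, raw, expected):
        assert classify_feeding_habit(raw) == expected

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("POM", "pPOM"),
            ("phytoplankton", "pPOM"),
            ("sediment", "sPOM"),
            ("sediment organic matter", "sPOM"),
            ("ice algae", "iPOM"),
            ("ice POM", "iPOM"),
            ("Laminaria", "macroalgae"),
            ("red algae", "macroalgae"),
        ],
    )
    def test_endmember_synonymization(self, raw, expected):
        assert synonymize_endmember(raw) == expected

    def test_unknown_terms_raise_not_coerce(self):
        with pytest.raises(UnmappedVocabularyError):
            classify_feeding_habit("chemoautotroph")
        with pytest.raises(UnmappedVocabularyError):
            synonymize_endmember("mystery goo")


class TestDatasetInvariants:
    def test_origin_must_match_earliest_date(self, records_csv):
        ds, _ = parse_records(records_csv([{"date": "2005-01-01"}, {}]))
        import datetime

        with pytest.raises(ValueError, match="origin_date"):
            Dataset(frame=ds.frame, origin_date=datetime.date(2001, 1, 1))

    def test_duplicate_record_ids_rejected(self, records_csv):
        ds, _ = parse_records(records_csv([{}, {}]))
        frame = ds.frame.copy()
        frame.index = ["a", "a"]
        with pytest.raises(ValueError, match="unique"):
            Dataset(frame=frame, origin_date=ds.origin_date)
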