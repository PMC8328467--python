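import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefchrono.binning import ReefZone, TimeBin
from reefchrono.life_history import LifeHistoryGroup, guild_members
from reefchrono.records import (
    SPECIES_COLUMNS,
    BinnedOccurrenceMatrix,
    SurveyRecord,
    aggregate_replicates,
    filter_full_complement,
    harmonize_records,
)
from reefchrono.taxa import ALL_SPECIES, SpeciesGroup


def rec(taxa, site="S1", country="CU", rep=None, **kw):
    defaults = dict(
        survey_id="sv1", country=country, site=site, year_or_age=1987, depth_m=4.0,
        habitat="forereef", replicate_id=rep,
    )
    defaults.update(kw)
    return SurveyRecord(taxa=taxa, **defaults)


class TestAggregateReplicates:
    def test_or_rule(self):
        merged = aggregate_replicates(
            [rec({"AGARICIA": 1}), rec({"AGARICIA": 0}), rec({"AGARICIA": 0})]
        )
        assert merged.taxa["AGARICIA"] == 1

    def test_absent_in_all(self):
        merged = aggregate_replicates([rec({"AGARICIA": 0}), rec({"AGARICIA": 0})])
        assert merged.taxa["AGARICIA"] == 0

    def test_disjoint_subsets_union(self):
        """Replicates scoring disjoint species: union of scored, OR of presence."""
        merged = aggregate_replicates(
            [rec({"ACER": 1, "APAL": 0}), rec({"ORBICELLA": 0}), rec({"APAL": 1})]
        )
        assert merged.taxa == {"ACER": 1, "APAL": 1, "ORBICELLA": 0}

    def test_conflicting_country_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            aggregate_replicates([rec({}, country="CU"), rec({}, country="JM")])

    @given(
        presences=st.lists(
            st.dictionaries(
                st.sampled_from(["ACER", "APAL", "MCAV"]), st.integers(0, 1), max_size=3
            ),
            min_size=1,
            max_size=5,
        ),
        perm_seed=st.integers(0, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_order_invariance(self, presences, perm_seed):
        recs = [rec(t) for t in presences]
        shuffled = list(np.random.default_rng(perm_seed).permutation(recs))
        assert aggregate_replicates(recs).taxa == aggregate_replicates(shuffled).taxa


def _matrix(rows: dict[str, dict], countries=None) -> BinnedOccurrenceMatrix:
    ids = list(rows)
    data = pd.DataFrame(
        [[rows[i].get(c, np.nan) for c in SPECIES_COLUMNS] for i in ids],
        index=ids,
        columns=SPECIES_COLUMNS,
    )
    countries = countries or {i: "CU" for i in ids}
    return BinnedOccurrenceMatrix(
        zone=ReefZone.CREST,
        bin=TimeBin.B1985_1989,
        data=data,
        country=pd.Series([countries[i] for i in ids], index=ids),
    )


class TestFullComplement:
    ST = list(guild_members(LifeHistoryGroup.STRESS_TOLERANT))
    WD = list(guild_members(LifeHistoryGroup.WEEDY))

    def test_complete_survey_retained(self):
        m = _matrix({"a": {sp.value: 1 for sp in self.ST}})
        assert filter_full_complement(m, self.ST).n_surveys == 1

    def test_partial_survey_dropped_per_group(self):
        scores = {sp.value: 0 for sp in self.ST if sp is not SpeciesGroup.MEANDRINA}
        scores.update({sp.value: 1 for sp in self.WD})
        m = _matrix({"a": scores})
        assert filter_full_complement(m, self.ST).n_surveys == 0  # missing MEANDRINA
        assert filter_full_complement(m, self.WD).n_surveys == 1

    def test_no_complete_rows_gives_empty(self):
        m = _matrix({"a": {"ACER": 1}, "b": {"MCAV": 0}})
        out = filter_full_complement(m, self.ST)
        assert out.n_surveys == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            filter_full_complement(_matrix({"a": {"ACER": 1}}), [])

    def test_retained_has_no_missing_and_monotone_in_group_size(self):
        rng = np.random.default_rng(0)
        rows = {}
        for i in range(40):
            rows[f"s{i}"] = {
                sp.value: int(rng.random() < 0.5)
                for sp in ALL_SPECIES
                if rng.random() > 0.2
            }
        m = _matrix(rows)
        sizes = []
        for k in range(1, len(ALL_SPECIES) + 1):
            out = filter_full_complement(m, list(ALL_SPECIES)[:k])
            cols = [sp.value for sp in ALL_SPECIES[:k]]
            assert not out.data[cols].isna().any().any()
            sizes.append(out.n_surveys)
        assert sizes == sorted(sizes, reverse=True)


class TestHarmonize:
    def test_curation_pipeline(self):
        records = [
            rec({"Acropora palmata": 1, "Favia fragum": 1}, site="A"),
            rec({"Acropora palmata": 0}, site="A", rep="r2"),  # replicate, OR -> 1
            rec({"Montastraea annularis": 1}, site="B", habitat="reef_flat"),  # excluded
            rec({"ACER": 1}, site="C", year_or_age=10_500, era="bp"),  # bin gap
            rec({"ACER": 1}, site="D", year_or_age=135_000, era="bp"),  # out of range
            rec({"Porites spp.": 1}, site="E", depth_m=12.0),  # midslope
        ]
        matrices, log = harmonize_records(records)
        crest = matrices[(ReefZone.CREST, TimeBin.B1985_1989)]
        assert crest.n_surveys == 1
        assert crest.data.loc["sv1", "APAL"] == 1.0
        assert np.isnan(crest.data.loc["sv1", "ACER"])  # never scored
        assert log["excluded_zone_habitat:reef_flat"] == 1
        assert log["excluded_age_gap"] == 1
        assert log["excluded_time_out_of_range"] == 1
        assert log["taxa_not_tracked"] == 1
        assert log["replicate_sets_aggregated"] == 1
        slope = matrices[(ReefZone.MIDSLOPE, TimeBin.B1985_1989)]
        assert slope.data.loc["sv1", "PORITES_BRANCHING"] == 1.0


class TestCsvRoundTrip:
    def test_long_and_wide_layouts(self, tmp_path):
        from reefchrono.ingest import read_survey_csv

        long = pd.DataFrame(
            {
                "survey_id": ["a", "a", "b"],
                "country": ["CU", "CU", "JM"],
                "site": ["A", "A", "B"],
                "year_or_age": [1987, 1987, 1992],
                "era": ["ad", "ad", "ad"],
                "depth_m": [4.0, 4.0, 12.0],
                "habitat": ["forereef"] * 3,
                "taxon": ["Acropora palmata", "Agaricia spp.", "Orbicella annularis"],
                "present": [1, 0, 1],
            }
        )
        p = tmp_path / "long.csv"
        long.to_csv(p, index=False)
        records = read_survey_csv(p, layout="long")
        assert len(records) == 2
        assert records[0].taxa == {"Acropora palmata": 1, "Agaricia spp.": 0}

        wide = pd.DataFrame(
            {
                "survey_id": ["a", "b"],
                "country": ["CU", "JM"],
                "year_or_age": [1987, 1992],
                "depth_m": [4.0, 12.0],
                "Acropora palmata": [1, None],
                "Orbicella annularis": [None, 1],
            }
        )
        pw = tmp_path / "wide.csv"
        wide.to_csv(pw, index=False)
        records = read_survey_csv(pw, layout="wide")
        assert records[0].taxa == {"Acropora palmata": 1}
        assert records[1].taxa == {"Orbicella annularis": 1}

    def test_matrix_csv_round_trip(self, tmp_path, full_complement_matrices):
        from reefchrono.ingest import read_matrix_csv, write_matrix_csv

        tb = TimeBin.B1985_1989
        m = full_complement_matrices[tb]
        path = tmp_path / "m.csv"
        write_matrix_csv(m, path)
        back = read_matrix_csv(path, m.zone, tb)
        pd.testing.assert_frame_equal(back.data, m.data)
        pd.testing.assert_series_equal(back.country, m.country, check_names=False)


class TestIngestConfig:
    def test_yaml_driven_ingest(self, tmp_path):
        import json

        import yaml

        from reefchrono.ingest import load_ingest_config, run_ingest

        surveys = pd.DataFrame(
            {
                "survey_id": ["a", "b"],
                "country": ["CU", "CU"],
                "site": ["A", "B"],
                "year_or_age": [1987, 1987],
                "era": ["ad", "ad"],
                "depth_m": [3.0, 4.0],
                "habitat": ["forereef", "forereef"],
                "taxon": ["Acropora palmata", "Acropora palmata"],
                "present": [1, 0],
            }
        )
        csv = tmp_path / "surveys.csv"
        surveys.to_csv(csv, index=False)
        cfg_path = tmp_path / "config.yaml"
        cfg_path.write_text(yaml.safe_dump({"input": str(csv), "layout": "long"}))
        out = tmp_path / "out"
        log = run_ingest(load_ingest_config(cfg_path), out)
        assert log["surveys_crest_B1985_1989"] == 2
        assert (out / "matrix_crest_B1985_1989.csv").exists()
        disk_log = json.loads((out / "curation_log.json").read_text())
        assert disk_log == log
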