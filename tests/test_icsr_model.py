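"""Data model, dictionaries, and line-listing I/O."""

import tempfile

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal.icsr_model import is_valid_atc

from conftest import make_report, write_listing


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestTypes:
    def test_report_requires_events(self):
        with pytest.raises(ValueError, match="no events"):
            make_report("R1", events=[])

    def test_age_range_enforced(self):
        with pytest.raises(ValueError):
            make_report("R1", age=131)
        assert make_report("R1", age=None).age_years is None

    def test_event_term_canonicalized(self):
        e = pv.EventEntry("  Confusional   state ")
        assert e.pt == "Confusional state"
        assert e.key == "confusional state"

    def test_drug_name_normalized_lowercase(self):
        d = pv.DrugEntry("  Citalopram ", frozenset(["N06AB04"]))
        assert d.drug_name == "citalopram"

    def test_invalid_atc_rejected(self):
        with pytest.raises(ValueError, match="ATC"):
            pv.DrugEntry("x", frozenset(["06AB"]))

    @pytest.mark.parametrize(
        "code,ok",
        [("N", True), ("N06", True), ("N06A", True), ("N06AB", True),
         ("N06AB04", True), ("n06", False), ("N6", False), ("N06AB0", False),
         ("N06AB041", False), ("", False)],
    )
    def test_atc_lexical_pattern(self, code, ok):
        assert is_valid_atc(code) is ok

    def test_duplicate_report_ids_rejected(self):
        with pytest.raises(pv.IntegrityError, match="duplicate"):
            pv.ReportSet([make_report("R1"), make_report("R1")])

    def test_counters_track_missing_sex(self):
        rs = pv.ReportSet([make_report("R1", sex=""), make_report("R2")])
        assert rs.counters == {"n_reports": 2, "n_missing_sex": 1, "n_missing_age": 0}


# ---------------------------------------------------------------------------
# class map
# ---------------------------------------------------------------------------

class TestClassMap:
    def test_citalopram_is_ssri(self, class_map):
        d = pv.DrugEntry("citalopram", frozenset(["N06AB04"]))
        assert pv.map_drug_to_classes(d, class_map) == {"SSRI"}

    def test_morphine_is_positive_control_only(self, class_map):
        d = pv.DrugEntry("morphine", frozenset(["N02AA01"]))
        assert pv.map_drug_to_classes(d, class_map) == {"POS_CONTROL"}

    def test_non_member_maps_to_empty_set(self, class_map):
        d = pv.DrugEntry("metformin", frozenset(["A10BA02"]))
        assert pv.map_drug_to_classes(d, class_map) == set()

    def test_snri_by_name_not_caught_by_other(self, class_map):
        # venlafaxine is ATC N06AX16 but must resolve only to SNRI
        d = pv.DrugEntry("venlafaxine", frozenset(["N06AX16"]))
        assert pv.map_drug_to_classes(d, class_map) == {"SNRI"}

    def test_classes_disjoint_at_name_level(self):
        with pytest.raises(pv.ConfigError, match="share drug names"):
            pv.ClassMap(
                classes={
                    "SNRI": pv.ClassDef(names={"venlafaxine"}),
                    "OTHER": pv.ClassDef(names={"venlafaxine"}),
                },
                controls={},
            )

    def test_order_independence(self, class_map):
        """Class mapping depends only on the entry, not on any list context."""
        entries = [
            pv.DrugEntry("mirtazapine", frozenset(["N06AX11"])),
            pv.DrugEntry("moclobemide", frozenset(["N06AG02"])),
        ]
        fwd = [pv.map_drug_to_classes(e, class_map) for e in entries]
        rev = [pv.map_drug_to_classes(e, class_map) for e in reversed(entries)]
        assert fwd == list(reversed(rev)) == [{"ALPHA2"}, {"MAOI"}]


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

class TestReadWrite:
    def test_minimal_join(self, tmp_path):
        rp, dp, ep = write_listing(
            tmp_path,
            [("R1", 70, "F", "Europe"), ("R2", 80, "M", "Asia")],
            [
                ("R1", "citalopram", "N06AB04", "suspect"),
                ("R1", "metformin", "A10BA02", "concomitant"),
                ("R2", "morphine", "N02AA01", "suspect"),
            ],
            [("R1", "Delirium"), ("R2", "Rash")],
        )
        rs = pv.read_reports(rp, dp, ep)
        assert len(rs) == 2
        by_id = {r.report_id: r for r in rs}
        assert len(by_id["R1"].drugs) == 2
        assert by_id["R2"].events[0].pt == "Rash"

    def test_dangling_event_row_names_offender(self, tmp_path):
        rp, dp, ep = write_listing(
            tmp_path,
            [("R1", 70, "F", "Europe")],
            [],
            [("R1", "Rash"), ("R99", "Delirium")],
        )
        with pytest.raises(pv.IntegrityError, match="R99"):
            pv.read_reports(rp, dp, ep)

    def test_missing_column_named(self, tmp_path):
        rp, dp, ep = write_listing(tmp_path, [("R1", 70, "F", "Europe")], [], [("R1", "Rash")])
        import pandas as pd

        pd.read_csv(rp).drop(columns=["sex"]).to_csv(rp, index=False)
        with pytest.raises(pv.FormatError, match="sex"):
            pv.read_reports(rp, dp, ep)

    def test_empty_sex_becomes_missing_and_counted(self, tmp_path):
        rp, dp, ep = write_listing(
            tmp_path,
            [("R1", 70, "", "Europe"), ("R2", 70, "M", "Asia")],
            [],
            [("R1", "Rash"), ("R2", "Rash")],
        )
        rs = pv.read_reports(rp, dp, ep)
        assert rs.counters["n_missing_sex"] == 1

    def test_duplicate_report_id_rejected(self, tmp_path):
        rp, dp, ep = write_listing(
            tmp_path,
            [("R1", 70, "F", "Europe"), ("R1", 71, "M", "Asia")],
            [],
            [("R1", "Rash")],
        )
        with pytest.raises(pv.IntegrityError, match="R1"):
            pv.read_reports(rp, dp, ep)

    def test_zero_event_reports_rejected(self, tmp_path):
        rp, dp, ep = write_listing(
            tmp_path,
            [("R1", 70, "F", "Europe"), ("R2", 80, "M", "Asia")],
            [],
            [("R1", "Rash")],
        )
        rs = pv.read_reports(rp, dp, ep)
        assert rs.report_ids() == ["R1"]

    def test_duplicate_drug_rows_collapse_keeping_most_causal_role(self, tmp_path):
        rp, dp, ep = write_listing(
            tmp_path,
            [("R1", 70, "F", "Europe")],
            [
                ("R1", "citalopram", "N06AB04", "concomitant"),
                ("R1", "citalopram", "", "suspect"),
            ],
            [("R1", "Rash")],
        )
        rs = pv.read_reports(rp, dp, ep)
        (drug,) = rs.reports[0].drugs
        assert drug.role == "suspect"
        assert drug.atc_codes == frozenset(["N06AB04"])

    def test_unknown_drug_resolves_to_empty_atc(self, tmp_path):
        rp, dp, ep = write_listing(
            tmp_path,
            [("R1", 70, "F", "Europe")],
            [("R1", "notadrugxyz", "", "suspect")],
            [("R1", "Rash")],
        )
        rs = pv.read_reports(rp, dp, ep)
        assert rs.reports[0].drugs[0].atc_codes == frozenset()

    def test_round_trip_identity(self, tmp_path):
        rs, _ = pv.generate_reports(pv.preset_scenario("study_like", n_reports=100, seed=3))
        paths = pv.write_reports(rs, tmp_path / "out")
        back = pv.read_reports(**paths)
        assert back.reports == rs.reports

    def test_round_trip_empty_set(self, tmp_path):
        paths = pv.write_reports(pv.ReportSet([]), tmp_path / "empty")
        for p in paths.values():
            assert p.read_text().count("\n") == 1  # header only

    def test_multi_atc_semicolon_round_trip(self, tmp_path):
        r = pv.Report(
            report_id="R1",
            age_years=70,
            sex="F",
            region="Europe",
            drugs=(pv.DrugEntry("mysteron", frozenset(["A01AA01", "B01AB02"]), "suspect"),),
            events=(pv.EventEntry("Rash"),),
        )
        paths = pv.write_reports(pv.ReportSet([r]), tmp_path / "multi")
        assert ";" in paths["drugs_path"].read_text()
        back = pv.read_reports(**paths)
        assert back.reports[0].drugs[0].atc_codes == frozenset(["A01AA01", "B01AB02"])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(min_value=1, max_value=40), st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_property(self, n, seed):
        rs, _ = pv.generate_reports(pv.preset_scenario("study_like", n_reports=n, seed=seed))
        with tempfile.TemporaryDirectory() as out:
            back = pv.read_reports(**pv.write_reports(rs, out))
        assert back.reports == rs.reports


# ---------------------------------------------------------------------------
# study config
# ---------------------------------------------------------------------------

class TestStudyConfig:
    def test_empty_file_gives_full_defaults(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("")
        cfg = pv.load_study_config(p)
        assert cfg.min_age == 65
        assert cfg.frequent_drug_threshold == 1000
        assert cfg.definition("primary").terms == frozenset(
            {"Delirium", "Confusional state", "Disorientation"}
        )
        assert set(cfg.class_map.labels) == {"NSMRI", "SSRI", "SNRI", "MAOI", "ALPHA2", "OTHER"}

    def test_override_primary_definition(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("event_definitions:\n  primary:\n    - Delirium\n    - Confusional state\n")
        cfg = pv.load_study_config(p)
        assert cfg.definition("primary").terms == frozenset({"Delirium", "Confusional state"})

    def test_unknown_class_label_names_key(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("class_map:\n  SSRIS:\n    atc_prefixes: [N06AB]\n")
        with pytest.raises(pv.ConfigError, match="SSRIS"):
            pv.load_study_config(p)

    def test_malformed_atc_prefix_names_key(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("class_map:\n  SSRI:\n    atc_prefixes: ['06AB']\n")
        with pytest.raises(pv.ConfigError, match="SSRI"):
            pv.load_study_config(p)

    def test_empty_event_definition_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("event_definitions:\n  primary: []\n")
        with pytest.raises(pv.ConfigError, match="primary"):
            pv.load_study_config(p)

    def test_bands_must_partition(self):
        with pytest.raises(pv.ConfigError, match="band"):
            pv.StudyConfig(age_bands=((65, 74), (76, None)))
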