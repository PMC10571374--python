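"""Patient data model: derived markers, discretization, stratification, CSV."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crpopf.cohort import (
    NON_PDAC,
    PDAC,
    Cohort,
    CohortError,
    MarkerDefinition,
    SchemaError,
    compute_bmi,
    compute_conut,
    compute_mpd_index,
    compute_pni,
    default_panel,
    discretize_record,
    load_panel,
    read_cohort_csv,
    stratify_by_diagnosis,
    write_cohort_csv,
)
from conftest import make_record


class TestDerivedMarkers:
    @pytest.mark.parametrize(
        "size,thickness,expected",
        [(5.0, 10.0, 0.5), (13.0, 13.0, 1.0), (4.0, 13.0, 4.0 / 13.0)],
    )
    def test_mpd_index(self, size, thickness, expected):
        assert compute_mpd_index(size, thickness) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "height,weight,expected",
        [(1.0, 25.0, 25.0), (2.0, 100.0, 25.0), (1.6, 57.0, 57.0 / 2.56)],
    )
    def test_bmi(self, height, weight, expected):
        assert compute_bmi(height, weight) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "albumin,lymphocytes,expected",
        [(4.0, 1540, 47.7), (1.0, 200, 11.0), (3.5, 1500, 42.5)],
    )
    def test_pni(self, albumin, lymphocytes, expected):
        assert compute_pni(albumin, lymphocytes) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "albumin,lymphocytes,cholesterol,expected",
        [(4.0, 2000, 200, 0), (2.0, 500, 80, 12), (3.2, 1300, 150, 4)],
    )
    def test_conut(self, albumin, lymphocytes, cholesterol, expected):
        assert compute_conut(albumin, lymphocytes, cholesterol) == expected

    @pytest.mark.parametrize(
        "fn,args",
        [
            (compute_mpd_index, (0.0, 13.0)),
            (compute_mpd_index, (4.0, -1.0)),
            (compute_bmi, (0.0, 60.0)),
            (compute_pni, (4.0, 0.0)),
            (compute_conut, (4.0, 1500.0, -5.0)),
        ],
    )
    def test_nonpositive_inputs_rejected(self, fn, args):
        with pytest.raises(CohortError):
            fn(*args)


class TestRecordValidation:
    def test_inconsistent_bmi_rejected(self):
        with pytest.raises(CohortError, match="bmi"):
            make_record(0, bmi=30.0, weight=22.0 * 1.6**2)

    def test_inconsistent_mpd_index_rejected(self):
        with pytest.raises(CohortError, match="mpd_index"):
            make_record(0, mpd_index=0.8, mpd_size=0.25 * 13.0)

    def test_unknown_diagnosis_rejected(self):
        with pytest.raises(CohortError, match="diagnosis"):
            make_record(0, diagnosis="benign")

    def test_derived_markers_consistent_to_1e9(self):
        r = make_record(3, mpd_index=0.31, bmi=26.5)
        assert abs(r.mpd_index - r.mpd_size / r.parenchymal_thickness) < 1e-9
        assert abs(r.bmi - r.weight / r.height**2) < 1e-9
        assert abs(r.pni - (10 * r.albumin + 0.005 * r.lymphocytes)) < 1e-9


class TestDiscretization:
    @pytest.mark.parametrize(
        "mpd_index,bmi,expected_bins",
        [
            (0.33, 22.3, (1, 0)),  # cohort-typical values vs the 0.3 / 25 cut-offs
            (0.3, 25.0, (1, 1)),  # boundary goes to the upper bin
            (0.25, 26.0, (0, 1)),
        ],
    )
    def test_cutoff_convention(self, mpd_index, bmi, expected_bins):
        panel = (
            MarkerDefinition("mpd_index", "continuous", 0.3),
            MarkerDefinition("bmi", "continuous", 25.0),
        )
        r = make_record(0, mpd_index=mpd_index, bmi=bmi)
        assert discretize_record(r, panel).bins == expected_bins

    def test_binary_markers_and_full_panel(self):
        r = make_record(0, sex="female", diabetes=True, conut=3)
        profile = discretize_record(r, default_panel())
        by_name = dict(zip(profile.marker_names, profile.bins))
        assert by_name["sex"] == 0
        assert by_name["diabetes"] == 1
        assert by_name["conut"] == 1  # CONUT >= 3
        assert by_name["diagnosis"] == 1  # PDAC

    def test_missing_marker_named_in_error(self):
        r = make_record(0, vfa=None)
        with pytest.raises(CohortError, match="vfa"):
            discretize_record(r, default_panel())

    @given(value=st.floats(0.01, 5.0), bump=st.floats(0.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_raising_value_never_lowers_bin(self, value, bump):
        panel = (MarkerDefinition("mpd_index", "continuous", 0.3),)
        lo = discretize_record(make_record(0, mpd_index=value), panel).bins[0]
        hi = discretize_record(make_record(0, mpd_index=value + bump), panel).bins[0]
        assert hi >= lo

    def test_continuous_marker_requires_cutoff(self):
        with pytest.raises(CohortError):
            MarkerDefinition("bmi", "continuous", None)
        with pytest.raises(CohortError):
            MarkerDefinition("diabetes", "binary", 1.0)


class TestStratification:
    @given(flags=st.lists(st.booleans(), min_size=0, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_partition(self, flags):
        records = tuple(
            make_record(i, diagnosis=PDAC if f else NON_PDAC)
            for i, f in enumerate(flags)
        )
        cohort = Cohort(records)
        pdac, non = stratify_by_diagnosis(cohort)
        assert len(pdac) + len(non) == len(cohort)
        assert {r.id for r in pdac.records} | {r.id for r in non.records} == {
            r.id for r in cohort.records
        }
        assert all(r.diagnosis == PDAC for r in pdac.records)
        assert all(r.diagnosis == NON_PDAC for r in non.records)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(CohortError, match="T000"):
            Cohort((make_record(0), make_record(0, diagnosis=NON_PDAC)))


class TestCsvRoundTrip:
    def test_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_cohort_csv(Cohort(()), path)
        assert len(read_cohort_csv(path)) == 0

    def test_round_trip_identity(self, tmp_path):
        records = (
            make_record(0, mpd_index=0.33, bmi=22.3),
            make_record(1, diagnosis=NON_PDAC, sex="female", cr_popf=True),
            make_record(2, vfa=None, sarcopenia=None, cr_popf=None),
        )
        path = tmp_path / "cohort.csv"
        write_cohort_csv(Cohort(records), path)
        back = read_cohort_csv(path)
        assert back.records == records

    def test_duplicate_id_names_offender(self, tmp_path):
        path = tmp_path / "dup.csv"
        write_cohort_csv(Cohort((make_record(0), make_record(1))), path)
        text = path.read_text().replace("T001", "T000")
        path.write_text(text)
        with pytest.raises(SchemaError, match="T000"):
            read_cohort_csv(path)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_cohort_csv(Cohort((make_record(0),)), path)
        lines = path.read_text().splitlines()
        lines[0] += ",mystery"
        lines[1] += ",1"
        path.write_text("\n".join(lines))
        with pytest.raises(SchemaError, match="mystery"):
            read_cohort_csv(path)

    def test_unparseable_value_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_cohort_csv(Cohort((make_record(0), make_record(1))), path)
        path.write_text(path.read_text().replace("T001,PDAC,male,69.0", "T001,PDAC,male,old"))
        with pytest.raises(SchemaError, match="row 3"):
            read_cohort_csv(path)


def test_panel_yaml_loading(tmp_path):
    path = tmp_path / "panel.yaml"
    path.write_text(
        "- {name: mpd_index, kind: continuous, cutoff: 0.3}\n"
        "- {name: sarcopenia, kind: binary}\n"
    )
    panel = load_panel(path)
    assert panel[0].cutoff == 0.3
    assert panel[1].kind == "binary"
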