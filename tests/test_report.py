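import numpy as np
import pytest

import taarip as T
from taarip.report import (
    NORMAL_FLAG, ABNORMAL_FLAG, UNAVAILABLE,
    flag_by_deviation, flag_by_range, flag_spo2,
)


class TestDeviationRule:
    def test_value_at_mean_is_normal(self):
        assert flag_by_deviation(20.0, 20.0) == NORMAL_FLAG

    def test_boundary_inclusive_both_sides(self):
        assert flag_by_deviation(24.0, 20.0) == NORMAL_FLAG   # exactly +20%
        assert flag_by_deviation(16.0, 20.0) == NORMAL_FLAG   # exactly -20%

    def test_just_past_boundary_is_abnormal(self):
        assert flag_by_deviation(24.0 + 1e-9, 20.0) == ABNORMAL_FLAG
        assert flag_by_deviation(16.0 - 1e-9, 20.0) == ABNORMAL_FLAG

    def test_one_sided_above_for_phase(self):
        assert flag_by_deviation(1.0, 10.0, sided="above") == NORMAL_FLAG
        assert flag_by_deviation(12.0 + 1e-9, 10.0, sided="above") == ABNORMAL_FLAG

    def test_missing_value_unavailable(self):
        assert flag_by_deviation(None, 20.0) == UNAVAILABLE
        assert flag_by_deviation(float("nan"), 20.0) == UNAVAILABLE

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            flag_by_deviation(10.0, 0.0)


class TestRangeAndSpo2Rules:
    @pytest.mark.parametrize("value,expected", [
        (40.0, NORMAL_FLAG), (35.0, NORMAL_FLAG), (45.0, NORMAL_FLAG),
        (46.0, ABNORMAL_FLAG), (34.9, ABNORMAL_FLAG), (None, UNAVAILABLE),
    ])
    def test_etco2_range_inclusive(self, value, expected):
        assert flag_by_range(value, 35.0, 45.0) == expected

    @pytest.mark.parametrize("value,expected", [
        (96.0, NORMAL_FLAG), (95.0, ABNORMAL_FLAG),  # strictly above 95
        (95.0001, NORMAL_FLAG), (None, UNAVAILABLE),
    ])
    def test_spo2_strictly_above_cutoff(self, value, expected):
        assert flag_spo2(value) == expected


def _series(phase=5.0, rc=50.0, lbi=1.02, rr=16.0, n=10):
    return T.IndexSeries(
        window_starts=np.arange(n, dtype=float),
        phase_deg=np.full(n, phase),
        rc_percent=np.full(n, rc),
        lbi=np.full(n, lbi),
        rr_bpm=rr, window_s=30.0, step_s=5.0,
    )


@pytest.fixture
def refs():
    return T.ReferenceRanges.default()


def test_default_references_load_and_cover_ages(refs):
    assert refs.band_for_age(12.0) is not None
    assert refs.band_for_age(0.5) is not None
    assert refs.band_for_age(None) is None
    assert refs.etco2_range == (35.0, 45.0)


def test_report_normal_subject_all_normal(refs):
    vitals = T.VitalSigns(subject_id="s", rr=16.0, etco2=40.0, spo2=98.0,
                          age_years=14.0)
    rep = T.build_report(_series(), vitals, (0.05, "normal"), refs, subject_id="s")
    assert all(v == NORMAL_FLAG for v in rep.flags.values())


def test_report_asynchronous_subject_flags_phase_and_icp(refs):
    vitals = T.VitalSigns(subject_id="s", rr=16.0, etco2=40.0, spo2=98.0,
                          age_years=14.0)
    rep = T.build_report(_series(phase=120.0, lbi=1.8), vitals, (0.99, "abnormal"),
                         refs, subject_id="s")
    assert rep.flags["phase"] == ABNORMAL_FLAG
    assert rep.flags["icp_classifier"] == ABNORMAL_FLAG
    assert rep.flags["lbi"] == ABNORMAL_FLAG
    assert rep.flags["spo2"] == NORMAL_FLAG


def test_report_missing_vitals_degrade_to_unavailable(refs):
    rep = T.build_report(_series(), None, None, refs, subject_id="s", age_years=14.0)
    assert rep.flags["etco2"] == UNAVAILABLE
    assert rep.flags["spo2"] == UNAVAILABLE
    assert rep.flags["icp_classifier"] == UNAVAILABLE
    # rr falls back to the signal-derived rate
    assert rep.flags["rr"] == NORMAL_FLAG


def test_report_age_outside_reference_table(refs):
    vitals = T.VitalSigns(subject_id="s", rr=16.0, etco2=40.0, spo2=98.0)
    rep = T.build_report(_series(), vitals, None, refs, subject_id="s", age_years=None)
    assert rep.flags["rr"] == UNAVAILABLE
    assert rep.flags["phase"] == UNAVAILABLE
    assert rep.flags["etco2"] == NORMAL_FLAG  # range rules need no age


def test_infinite_lbi_flags_abnormal(refs):
    series = _series()
    series.lbi[:] = np.inf
    vitals = T.VitalSigns(subject_id="s", rr=16.0, etco2=40.0, spo2=98.0,
                          age_years=14.0)
    rep = T.build_report(series, vitals, None, refs, subject_id="s")
    assert rep.flags["lbi"] == ABNORMAL_FLAG


def test_reports_round_trip_and_frame(tmp_path, refs):
    vitals = T.VitalSigns(subject_id="s", rr=16.0, etco2=40.0, spo2=98.0,
                          age_years=14.0)
    rep = T.build_report(_series(), vitals, (0.1, "normal"), refs, subject_id="s",
                         clinical_diagnosis="none noted", surgery="none")
    path = tmp_path / "reports.json"
    T.save_reports([rep], path)
    back = T.load_reports(path)
    assert back[0].to_dict() == rep.to_dict()
    df = T.reports_to_frame(back)
    assert df.loc[0, "subject_id"] == "s"
    assert df.loc[0, "icp_classifier"] == NORMAL_FLAG


def test_invalid_flag_state_rejected():
    with pytest.raises(ValueError):
        T.AssessmentReport(subject_id="s", age_years=1.0, flags={"rr": "maybe"})


def test_reference_ranges_json_round_trip(tmp_path, refs):
    path = tmp_path / "refs.json"
    refs.to_json(path)
    back = T.ReferenceRanges.from_json(path)
    assert back == refs
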