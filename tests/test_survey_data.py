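"""Survey table I/O, validation and collar-detection matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dosabund import (
    DetectionModelSpec,
    GroupRecord,
    SurveyDataset,
    TelemetryFix,
    match_collar_detections,
    read_survey_table,
    validate_dataset,
    write_survey_table,
)
from dosabund.survey_data import SurveyValidationError, read_telemetry_table


def _write(tmp_path, text, name="survey.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "group_id,survey_id,detected_obs1,detected_obs2,collared,size_best\n"


class TestReadSurveyTable:
    def test_parses_valid_rows(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER + "a,s,1,1,0,3\nb,s,1,0,0,2\nc,s,0,1,0,5\n",
        )
        ds = read_survey_table(path)
        assert ds.n_groups == 3
        assert ds.n_collared == 0
        assert [r.size_best for r in ds.records] == [3, 2, 5]
        # unspecified optional covariates come back missing
        assert ds.records[0].forest is None
        assert ds.records[0].pct_snow is None

    def test_unobservable_row_rejected_with_row_index(self, tmp_path):
        path = _write(tmp_path, HEADER + "a,s,1,1,0,3\nb,s,0,0,0,2\n")
        with pytest.raises(SurveyValidationError) as err:
            read_survey_table(path)
        assert any("row 2" in msg and "unobservable" in msg for msg in err.value.issues)

    def test_missing_required_column(self, tmp_path):
        path = _write(tmp_path, "group_id,detected_obs1,size_best\na,1,3\n")
        with pytest.raises(SurveyValidationError, match="missing required column"):
            read_survey_table(path)

    def test_non_binary_detection_rejected(self, tmp_path):
        path = _write(tmp_path, HEADER + "a,s,2,1,0,3\n")
        with pytest.raises(SurveyValidationError, match="detected_obs1"):
            read_survey_table(path)

    def test_duplicate_group_id_rejected(self, tmp_path):
        path = _write(tmp_path, HEADER + "a,s,1,1,0,3\na,s,1,0,0,2\n")
        with pytest.raises(SurveyValidationError, match="duplicate group_id"):
            read_survey_table(path)


class TestWriteSurveyTable:
    def test_empty_dataset_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_survey_table(SurveyDataset([]), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("group_id,survey_id,detected_obs1")

    def test_missing_cells_round_trip_to_missing(self, tmp_path):
        rec = GroupRecord(
            group_id="a", detected_obs1=1, detected_obs2=0, size_best=4,
            pct_conceal=0.25, pct_snow=None, forest=1,
        )
        path = tmp_path / "m.csv"
        write_survey_table(SurveyDataset([rec], survey_label="x"), path)
        back = read_survey_table(path, survey_label="x")
        assert back.records[0].pct_snow is None
        assert back.records[0].pct_conceal == 0.25
        assert back.records == [rec]


@st.composite
def survey_datasets(draw):
    n = draw(st.integers(min_value=0, max_value=12))
    records = []
    for i in range(n):
        collared = draw(st.integers(0, 1))
        if collared:
            y1, y2 = draw(st.tuples(st.integers(0, 1), st.integers(0, 1)))
        else:
            y1, y2 = draw(st.sampled_from([(0, 1), (1, 0), (1, 1)]))
        records.append(
            GroupRecord(
                group_id=f"g{i}",
                survey_id="hyp",
                detected_obs1=y1,
                detected_obs2=y2,
                collared=collared,
                size_obs1=draw(st.one_of(st.none(), st.integers(1, 40))) if y1 else None,
                size_obs2=draw(st.one_of(st.none(), st.integers(1, 40))) if y2 else None,
                size_best=draw(st.integers(1, 40)),
                forest=draw(st.one_of(st.none(), st.integers(0, 1))),
                pct_conceal=draw(st.one_of(st.none(), st.floats(0, 1, allow_nan=False))),
                pct_snow=draw(st.one_of(st.none(), st.floats(0, 1, allow_nan=False))),
                moving=draw(st.one_of(st.none(), st.integers(0, 1))),
                size_imputed=0 if (y1 or y2) else 1,
            )
        )
    return SurveyDataset(records, survey_label="hyp")


@settings(max_examples=40, derandomize=True, deadline=None)
@given(survey_datasets())
def test_round_trip_identity(tmp_path_factory, dataset):
    """read(write(d)) reproduces every record field-for-field."""
    path = tmp_path_factory.mktemp("rt") / "d.csv"
    write_survey_table(dataset, path)
    back = read_survey_table(path, survey_label="hyp")
    assert back.records == dataset.records


class TestValidateDataset:
    def test_spec_covariate_missing_names_group(self):
        spec = DetectionModelSpec(covariates=("forest",))
        ds = SurveyDataset(
            [
                GroupRecord(group_id="ok", detected_obs1=1, size_best=2, forest=1),
                GroupRecord(group_id="bad", detected_obs2=1, size_best=2, forest=None),
            ]
        )
        issues = validate_dataset(ds, spec)
        assert len(issues) == 1
        assert "bad" in issues[0] and "forest" in issues[0]

    def test_observer_only_spec_on_valid_dataset_is_clean(self, lp_dataset):
        assert validate_dataset(lp_dataset, DetectionModelSpec()) == []

    def test_undetected_collared_without_size_source_flagged(self):
        ds = SurveyDataset(
            [GroupRecord(group_id="c", collared=1, size_best=8, size_imputed=0)]
        )
        issues = validate_dataset(ds)
        assert len(issues) == 1 and "no source" in issues[0]


def _fix(collar, minutes, x, y):
    return TelemetryFix(collar, pd.Timestamp("2020-02-11 08:00") + pd.Timedelta(minutes=minutes), x, y)


class TestMatchCollarDetections:
    T0 = pd.Timestamp("2020-02-11 08:00")

    def test_fix_within_thresholds_matches(self):
        res = match_collar_detections(
            [("g1", self.T0, 0.0, 0.0)], [_fix("A", 30, 10.0, 0.0)],
            max_time_gap="2h", max_distance=500.0,
        )
        assert res.matches == {"g1": ["A"]}
        assert res.missed_collars == []

    def test_distant_fix_reported_missed(self):
        res = match_collar_detections(
            [("g1", self.T0, 0.0, 0.0)], [_fix("A", 30, 10000.0, 0.0)],
            max_time_gap="2h", max_distance=500.0,
        )
        assert res.matches == {}
        assert res.missed_collars == ["A"]

    def test_spatial_tie_broken_by_time(self):
        detections = [
            ("d1", self.T0, 0.0, 0.0),
            ("d2", self.T0 + pd.Timedelta(minutes=50), 1000.0, 0.0),
        ]
        # each fix is 100 m from one detection; the collar's best pair is the
        # one nearer in time, which belongs to d2
        fixes = [
            TelemetryFix("A", self.T0 + pd.Timedelta(minutes=55), 100.0, 0.0),
            TelemetryFix("A", self.T0 + pd.Timedelta(minutes=55), 900.0, 0.0),
        ]
        res = match_collar_detections(detections, fixes, "2h", 500.0)
        assert res.matches == {"d2": ["A"]}

    def test_empty_fixes_raises(self):
        with pytest.raises(ValueError, match="empty"):
            match_collar_detections([("g1", self.T0, 0, 0)], [])

    def test_permutation_invariance_and_conservation(self):
        rng = np.random.default_rng(5)
        detections = [
            (f"d{i}", self.T0 + pd.Timedelta(minutes=int(rng.integers(0, 120))),
             float(rng.uniform(0, 5000)), float(rng.uniform(0, 5000)))
            for i in range(6)
        ]
        fixes = [
            _fix(f"C{j}", int(rng.integers(0, 180)), float(rng.uniform(0, 6000)),
                 float(rng.uniform(0, 6000)))
            for j in range(8)
            for _ in range(2)
        ]
        res = match_collar_detections(detections, fixes, "1h", 1500.0)
        shuffled = match_collar_detections(detections[::-1], fixes[::-1], "1h", 1500.0)
        assert res == shuffled
        n_collars = len({f.collar_id for f in fixes})
        assert res.n_matched + len(res.missed_collars) == n_collars


def test_read_telemetry_table(tmp_path):
    p = tmp_path / "fixes.csv"
    p.write_text(
        "collar_id,timestamp,x,y\nB,2020-02-11T10:00:00,5.0,6.0\nA,2020-02-11T08:00:00,1.0,2.0\n"
    )
    fixes = read_telemetry_table(p)
    assert [f.collar_id for f in fixes] == ["A", "B"]
    assert fixes[0].x == 1.0
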