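"""Keypoint/angle file readers, writers, and gap interpolation."""

import json

import numpy as np
import pytest

from sitstand.errors import FormatError, GapError, ParseError
from sitstand.keypoint_io import (
    KeypointSequence2D,
    KeypointSequence3D,
    interpolate_gaps,
    read_alphapose_json,
    read_angle_series_csv,
    read_keypoints3d,
    write_angle_series_csv,
    write_keypoints3d,
)
from sitstand.kinematics import AngleSeries
from sitstand.schemes import H36M17

from conftest import make_alphapose_records


class TestAlphaPoseReader:
    def test_conformant_fixture_matches_hand_built_arrays(self, alphapose_file):
        path, records = alphapose_file
        seq = read_alphapose_json(path)
        assert (seq.n_frames, seq.n_joints) == (3, 17)
        for f, rec in enumerate(records):
            triples = np.asarray(rec["keypoints"]).reshape(17, 3)
            np.testing.assert_array_equal(seq.coords[f], triples[:, :2])
            np.testing.assert_array_equal(seq.confidence[f], triples[:, 2])

    def test_empty_record_list_gives_zero_frames(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text("[]")
        assert read_alphapose_json(path).n_frames == 0

    def test_keypoints_not_divisible_by_three_is_format_error(self, tmp_path):
        rng = np.random.default_rng(0)
        records = make_alphapose_records(1, rng)
        records[0]["keypoints"] = records[0]["keypoints"][:50]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(records))
        with pytest.raises(FormatError):
            read_alphapose_json(path)

    def test_wrong_joint_count_is_format_error(self, tmp_path):
        records = [{"image_id": "0.jpg", "keypoints": [1.0, 2.0, 0.9] * 16}]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(records))
        with pytest.raises(FormatError):
            read_alphapose_json(path)

    def test_malformed_json_is_parse_error(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("[{]")
        with pytest.raises(ParseError):
            read_alphapose_json(path)

    def test_per_detection_dialect_keeps_best_detection_per_frame(self, tmp_path):
        rng = np.random.default_rng(1)
        records = make_alphapose_records(2, rng)
        # second, higher-scoring detection on frame 0
        dup = dict(records[0])
        dup["keypoints"] = (np.asarray(records[0]["keypoints"]) + 5.0).tolist()
        dup["score"] = 9.0
        path = tmp_path / "multi.json"
        path.write_text(json.dumps([records[0], dup, records[1]]))
        seq = read_alphapose_json(path)
        assert seq.n_frames == 2
        expected = np.asarray(dup["keypoints"]).reshape(17, 3)[:, :2]
        np.testing.assert_array_equal(seq.coords[0], expected)

    def test_frames_ordered_by_numeric_image_id(self, tmp_path):
        rng = np.random.default_rng(2)
        records = make_alphapose_records(12, rng)
        shuffled = [records[i] for i in rng.permutation(12)]
        path = tmp_path / "shuffled.json"
        path.write_text(json.dumps(shuffled))
        seq = read_alphapose_json(path)
        assert seq.n_frames == 12
        # frame 10 must sort after frame 2 (numeric, not lexicographic)
        np.testing.assert_array_equal(
            seq.coords[10], np.asarray(records[10]["keypoints"]).reshape(17, 3)[:, :2]
        )


class TestKeypoints3D:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        seq = KeypointSequence3D(coords=rng.normal(size=(10, 17, 3)))
        path = write_keypoints3d(seq, tmp_path / "kp.csv")
        back = read_keypoints3d(path)
        assert back.n_frames == 10
        np.testing.assert_allclose(back.coords, seq.coords, rtol=0, atol=0)

    def test_wrong_joint_count_is_format_error(self, tmp_path):
        rng = np.random.default_rng(4)
        seq = KeypointSequence3D.__new__(KeypointSequence3D)  # bypass validation
        seq.coords = rng.normal(size=(5, 16, 3))
        seq.scheme = H36M17
        path = tmp_path / "bad.csv"
        import pandas as pd

        n_frames, n_joints = 5, 16
        pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_frames), n_joints),
                "joint": np.tile(np.arange(n_joints), n_frames),
                "x": seq.coords[..., 0].ravel(),
                "y": seq.coords[..., 1].ravel(),
                "z": seq.coords[..., 2].ravel(),
            }
        ).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_keypoints3d(path)

    def test_nan_coordinate_accepted_with_gap_flag(self, tmp_path):
        coords = np.zeros((4, 17, 3))
        coords[2, 5, :] = np.nan
        path = write_keypoints3d(KeypointSequence3D(coords=coords), tmp_path / "g.csv")
        back = read_keypoints3d(path)
        assert back.has_gaps

    def test_npy_reader(self, tmp_path):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(6, 17, 3))
        path = tmp_path / "kp.npy"
        np.save(path, arr)
        np.testing.assert_array_equal(read_keypoints3d(path).coords, arr)


class TestInterpolateGaps:
    def test_single_missing_frame_filled_with_midpoint(self):
        coords = np.zeros((3, 17, 3))
        coords[0, 0] = (0, 0, 0)
        coords[1, 0] = np.nan
        coords[2, 0] = (2, 2, 2)
        seq = KeypointSequence3D(coords=coords)
        out = interpolate_gaps(seq, max_gap=1)
        np.testing.assert_allclose(out.coords[1, 0], (1, 1, 1))

    def test_no_gaps_returns_identical_sequence(self):
        rng = np.random.default_rng(6)
        seq = KeypointSequence3D(coords=rng.normal(size=(5, 17, 3)))
        out = interpolate_gaps(seq)
        np.testing.assert_array_equal(out.coords, seq.coords)

    def test_run_longer_than_max_gap_raises(self):
        coords = np.zeros((8, 17, 3))
        coords[2:5, 3] = np.nan
        with pytest.raises(GapError):
            interpolate_gaps(KeypointSequence3D(coords=coords), max_gap=2)

    def test_gap_touching_boundary_raises(self):
        coords = np.zeros((5, 17, 3))
        coords[0, 2] = np.nan
        with pytest.raises(GapError):
            interpolate_gaps(KeypointSequence3D(coords=coords), max_gap=3)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(20, 17, 3))
        coords[5:8, 4] = np.nan
        coords[12, 9] = np.nan
        seq = KeypointSequence3D(coords=coords)
        once = interpolate_gaps(seq, max_gap=3)
        twice = interpolate_gaps(once, max_gap=3)
        np.testing.assert_array_equal(once.coords, twice.coords)

    def test_low_confidence_2d_frames_interpolated(self):
        coords = np.tile(np.arange(5, dtype=float)[:, None, None], (1, 17, 2))
        conf = np.full((5, 17), 0.9)
        conf[2, 0] = 0.1  # flickered detection
        coords[2, 0] = (99.0, 99.0)
        seq = KeypointSequence2D(coords=coords, confidence=conf)
        out = interpolate_gaps(seq, max_gap=2, min_confidence=0.3)
        np.testing.assert_allclose(out.coords[2, 0], (2.0, 2.0))
        # valid frames untouched
        np.testing.assert_array_equal(out.coords[3], seq.coords[3])


class TestAngleSeriesCSV:
    def _series(self, length=400):
        rng = np.random.default_rng(8)
        return AngleSeries(
            values={s: rng.uniform(30, 170, length) for s in
                    ("left_hip", "right_hip", "left_knee", "right_knee")},
            source_id="unit",
        )

    def test_round_trip_exact(self, tmp_path):
        series = self._series(57)
        path = write_angle_series_csv(series, tmp_path / "angles.csv")
        back = read_angle_series_csv(path)
        assert back == series

    def test_400_sample_file_shape(self, tmp_path):
        path = write_angle_series_csv(self._series(400), tmp_path / "a.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 401  # header + 400 data rows
        assert len(lines[0].split(",")) == 5  # sample + 4 sites

    def test_unknown_site_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample,left_hip,elbow\n0,90.0,10.0\n")
        with pytest.raises(FormatError):
            read_angle_series_csv(path)

    def test_missing_required_site_is_format_error(self, tmp_path):
        path = tmp_path / "partial.csv"
        path.write_text("sample,left_hip\n0,90.0\n")
        with pytest.raises(FormatError):
            read_angle_series_csv(path, required_sites=("left_hip", "left_knee"))
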