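"""Synthetic recording/cohort generator: determinism, severity structure,
and the end-to-end contrast the analysis is designed to detect."""

import numpy as np
import pytest

from sitstand.cohort import build_pools, classify_stiffness, group_mean_curves
from sitstand.errors import AggregationError, CohortError, ConfigurationError
from sitstand.keypoint_io import read_alphapose_json
from sitstand.kinematics import SITES, extract_angle_series
from sitstand.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_sts_recording,
    write_alphapose_projection,
)
from sitstand.wavelet_compare import compare_groups


class TestRecording:
    def test_default_recording_has_five_cycles_and_over_400_frames(
        self, default_recording
    ):
        assert default_recording.truth_cycles.n_cycles == 5
        assert default_recording.keypoints.n_frames > 400

    def test_same_seed_is_bit_identical(self):
        a = simulate_sts_recording(SimulationConfig(seed=9))
        b = simulate_sts_recording(SimulationConfig(seed=9))
        np.testing.assert_array_equal(a.keypoints.coords, b.keypoints.coords)
        assert a.truth_cycles.boundaries == b.truth_cycles.boundaries

    def test_different_seeds_differ(self):
        a = simulate_sts_recording(SimulationConfig(seed=1))
        b = simulate_sts_recording(SimulationConfig(seed=2))
        assert not np.array_equal(a.keypoints.coords, b.keypoints.coords)

    def test_full_stiffness_halves_range_of_motion(self):
        kwargs = dict(keypoint_noise_sd=0.0, variability=0.0, seed=0)
        supple = simulate_sts_recording(
            SimulationConfig(stiffness_factor=0.0, **kwargs)
        )
        stiff = simulate_sts_recording(
            SimulationConfig(stiffness_factor=1.0, **kwargs)
        )
        for rec, factor in ((supple, 1.0), (stiff, 0.5)):
            knee = rec.truth_angles["left_knee"]
            assert knee.max() - knee.min() == pytest.approx(85.0 * factor, abs=1e-6)

    def test_stiffness_stretches_transitions(self):
        kwargs = dict(keypoint_noise_sd=0.0, variability=0.0, seed=0)
        fast = simulate_sts_recording(SimulationConfig(stiffness_factor=0.0, **kwargs))
        slow = simulate_sts_recording(SimulationConfig(stiffness_factor=1.0, **kwargs))
        assert slow.keypoints.n_frames > fast.keypoints.n_frames

    @pytest.mark.parametrize(
        "bad",
        [
            dict(seated_knee_angle=0.0),
            dict(standing_hip_angle=181.0),
            dict(transition_duration=0.0),
            dict(stiffness_factor=1.5),
            dict(keypoint_noise_sd=-0.1),
            dict(n_cycles=0),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            simulate_sts_recording(SimulationConfig(**bad))

    def test_rigid_motion_leaves_extracted_angles_unchanged(self, default_recording):
        """Camera-pose invariance at the angle level: a random rotation plus
        translation of every keypoint changes no extracted angle by more than
        1e-9 degrees."""
        rng = np.random.default_rng(77)
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        shift = rng.normal(size=3) * 50
        moved = default_recording.keypoints
        from dataclasses import replace

        moved = replace(moved, coords=moved.coords @ rot.T + shift)
        base = extract_angle_series(default_recording.keypoints)
        transformed = extract_angle_series(moved)
        for site in SITES:
            np.testing.assert_allclose(
                transformed[site], base[site], atol=1e-9
            )

    def test_alphapose_projection_round_trips_through_reader(
        self, default_recording, tmp_path
    ):
        path = write_alphapose_projection(default_recording, tmp_path / "ap.json")
        seq = read_alphapose_json(path)
        assert seq.n_frames == default_recording.keypoints.n_frames
        assert seq.n_joints == 17
        assert (seq.confidence > 0).all()


class TestCohort:
    def test_same_seed_identical_rosters(self):
        a, _ = simulate_cohort(10, seed=5)
        b, _ = simulate_cohort(10, seed=5)
        assert [(s.subject_id, s.womac_stiffness, s.womac_function,
                 s.affected_sides) for s in a] == [
            (s.subject_id, s.womac_stiffness, s.womac_function, s.affected_sides)
            for s in b
        ]

    def test_classification_recovers_latent_labels(self):
        subjects, recordings = simulate_cohort(20, severity_mix=(0.5, 0.5), seed=7)
        labels = [classify_stiffness(s.womac_stiffness) for s in subjects]
        factors = [r.config.stiffness_factor for r in recordings]
        for label, factor in zip(labels, factors):
            assert label == ("mild" if factor < 0.4 else "severe")
        assert labels.count("mild") == labels.count("severe") == 10

    def test_all_mild_cohort_leaves_severe_pools_empty(self):
        subjects, _ = simulate_cohort(4, severity_mix=(1.0, 0.0), seed=3)
        pools = build_pools(subjects, "stiffness")
        assert all(
            count == 0
            for (_, level), count in pools.counts.items()
            if level == "severe"
        )
        with pytest.raises(AggregationError):
            group_mean_curves(pools)

    def test_too_small_group_raises(self):
        with pytest.raises(CohortError):
            simulate_cohort(3, severity_mix=(0.5, 0.5), seed=1)

    def test_severity_contrast_dominates_approximation_band(self, cohort40):
        """Mild and severe groups differ in slow components only, so the
        between-group cA difference must dwarf the cD difference at every
        site."""
        subjects, _ = cohort40
        means = group_mean_curves(build_pools(subjects, "stiffness"))
        for site, result in compare_groups(means).items():
            assert result.agg_cA >= 5.0 * result.agg_cD, site

    def test_between_group_gap_exceeds_same_severity_replication_gap(self):
        """agg_cA between mild and severe must clearly exceed agg_cA between
        two independently simulated same-severity cohorts."""
        subjects, _ = simulate_cohort(40, severity_mix=(0.5, 0.5), seed=11)
        between = compare_groups(
            group_mean_curves(build_pools(subjects, "stiffness"))
        )

        mild_a, _ = simulate_cohort(20, severity_mix=(1.0, 0.0), seed=21)
        mild_b, _ = simulate_cohort(20, severity_mix=(1.0, 0.0), seed=22)
        means_a = group_mean_curves(build_pools(mild_a, "stiffness"), allow_empty=True)
        means_b = group_mean_curves(build_pools(mild_b, "stiffness"), allow_empty=True)
        # relabel cohort B's mild means as the second level to reuse the comparator
        replication_curves = {}
        for site in SITES:
            replication_curves[(site, "mild")] = means_a[(site, "mild")]
            replication_curves[(site, "severe")] = means_b[(site, "mild")]
        same = compare_groups(replication_curves)
        for site in SITES:
            assert between[site].agg_cA >= 3.0 * same[site].agg_cA, site
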