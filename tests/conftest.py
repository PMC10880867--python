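"""Shared fixtures: programmatically built pose files and simulated data."""

import json

import numpy as np
import pytest

from sitstand.simulate import SimulationConfig, simulate_cohort, simulate_sts_recording


def make_alphapose_records(n_frames: int, rng: np.random.Generator) -> list[dict]:
    """Conformant AlphaPose-style records: one detection per frame, 17 joints."""
    records = []
    for f in range(n_frames):
        kp = np.column_stack(
            [
                rng.uniform(0, 640, 17),
                rng.uniform(0, 480, 17),
                rng.uniform(0.5, 1.0, 17),
            ]
        )
        records.append(
            {
                "image_id": f"{f}.jpg",
                "category_id": 1,
                "keypoints": kp.ravel().tolist(),
                "score": 2.0,
            }
        )
    return records


@pytest.fixture
def alphapose_file(tmp_path):
    """Write a 3-frame conformant results JSON; returns (path, records)."""
    rng = np.random.default_rng(42)
    records = make_alphapose_records(3, rng)
    path = tmp_path / "results.json"
    path.write_text(json.dumps(records))
    return path, records


@pytest.fixture(scope="session")
def default_recording():
    """One default-configuration recording (five cycles, default noise)."""
    return simulate_sts_recording(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_recording():
    """Same trajectories without keypoint noise, for closed-loop checks."""
    return simulate_sts_recording(SimulationConfig(seed=1, keypoint_noise_sd=0.0))


@pytest.fixture(scope="session")
def cohort40():
    """A 20-per-group simulated cohort shared by the slower end-to-end tests."""
    subjects, recordings = simulate_cohort(40, severity_mix=(0.5, 0.5), seed=11)
    return subjects, recordings
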