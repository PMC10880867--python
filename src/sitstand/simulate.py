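"""Synthetic sit-to-stand recordings and cohorts.

No patient videos accompany the analysis, so this module generates keypoint
recordings with the statistical structure the pipeline assumes: five
consecutive sit-to-stand repetitions, severity-dependent range of motion and
transition speed, per-cycle variability, and additive keypoint noise.

Model
-----
Hip and knee angle trajectories are built from raised-cosine ramps between
seated and standing values — one rise, a standing hold, one descent, and a
seated hold per cycle — with per-cycle multiplicative jitter on durations
and amplitude. Joint stiffness enters through a single ``stiffness_factor``
in [0, 1] that acts only on the *slow* components of the movement:

* effective range of motion = nominal range x (1 - 0.5 x stiffness_factor),
* effective transition time  = nominal time  x (1 + stiffness_factor),

so a maximally stiff subject opens the joints half as far and rises twice as
slowly. An optional small high-frequency tremor term (off by default) is the
only mechanism that puts severity signal into the detail band.

A strictly sagittal-plane skeleton is then posed by forward kinematics: the
shank is held vertical (as it nearly is in a sit-to-stand), the thigh is
placed to realize the commanded knee angle and the trunk to realize the
commanded hip angle, and the trunk chain (pelvis, spine, thorax, neck, head)
extends along the trunk direction. Arms are folded across the chest, static
in the trunk frame, per the test protocol. All load-bearing joints lie in
one plane, so the commanded angles are *exactly* recoverable from the
noiseless keypoints — the closed loop that validates the simulator and the
angle extractor against each other. Left and right sides coincide in the
noiseless limit; isotropic Gaussian keypoint noise then decorrelates them
the way pose-estimator jitter does. Lateral pelvis width, frontal/transverse
motion and camera models are deliberately out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cohort import SubjectRecord
from .errors import CohortError, ConfigurationError
from .keypoint_io import KeypointSequence3D
from .kinematics import (
    AngleSeries,
    CycleSegmentation,
    extract_angle_series,
)
from .preprocess import TARGET_LENGTH, normalize_angle_series
from .schemes import H36M17

__all__ = [
    "SimulationConfig",
    "SimulatedRecording",
    "simulate_sts_recording",
    "simulate_cohort",
    "write_alphapose_projection",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic sit-to-stand recording.

    Angle defaults describe a typical chair test: knees near 90° seated and
    almost straight standing, hips flexed seated and extended upright.
    ``segment_lengths`` are in the arbitrary reconstruction units of the
    lifting step (absolute scale carries no meaning downstream); ``foot`` is
    carried for completeness but the 17-joint layout has no toe joint to
    place with it.
    """

    n_cycles: int = 5
    frame_rate: float = 30.0
    seated_knee_angle: float = 90.0
    standing_knee_angle: float = 175.0
    seated_hip_angle: float = 95.0
    standing_hip_angle: float = 175.0
    transition_duration: float = 1.0  # seconds, seat->stand at stiffness 0
    hold_duration: float = 0.5  # seconds held at each posture
    stiffness_factor: float = 0.0
    variability: float = 0.05  # per-cycle multiplicative jitter scale
    keypoint_noise_sd: float = 0.005  # coordinate units
    tremor_amplitude: float = 0.0  # degrees, high-frequency term (off)
    tremor_frequency: float = 8.0  # Hz
    segment_lengths: dict[str, float] = field(
        default_factory=lambda: {
            "trunk": 0.50,
            "thigh": 0.45,
            "shank": 0.43,
            "foot": 0.25,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        angles = (
            self.seated_knee_angle,
            self.standing_knee_angle,
            self.seated_hip_angle,
            self.standing_hip_angle,
        )
        if any(not (0.0 < a <= 180.0) for a in angles):
            raise ConfigurationError("posture angles must lie in (0, 180]")
        if self.transition_duration <= 0 or self.hold_duration <= 0:
            raise ConfigurationError("durations must be positive")
        if not (0.0 <= self.stiffness_factor <= 1.0):
            raise ConfigurationError("stiffness_factor must lie in [0, 1]")
        if self.variability < 0 or self.keypoint_noise_sd < 0:
            raise ConfigurationError("noise scales must be non-negative")
        if self.n_cycles < 1 or self.frame_rate <= 0:
            raise ConfigurationError("need n_cycles >= 1 and frame_rate > 0")
        for name in ("trunk", "thigh", "shank"):
            if self.segment_lengths.get(name, 0.0) <= 0:
                raise ConfigurationError(f"segment length {name!r} must be > 0")


@dataclass
class SimulatedRecording:
    """One synthetic recording with its ground truth.

    ``truth_angles`` are the commanded joint-angle trajectories (identical
    left/right by construction); ``truth_cycles`` the frame indices of each
    cycle's rise start, mid-stand, and descent end.
    """

    keypoints: KeypointSequence3D
    truth_angles: AngleSeries
    truth_cycles: CycleSegmentation
    config: SimulationConfig


def _cycle_segments(config: SimulationConfig, rng: np.random.Generator):
    """Per-cycle (duration, phase) segment list with jittered timing/amplitude.

    Returns (segments, cycle_marks). Each segment is
    (duration_s, knee_from, knee_to, hip_from, hip_to); cycle_marks holds
    (rise_start_s, stand_mid_s, descent_end_s) per cycle.
    """
    sf = config.stiffness_factor
    trans = config.transition_duration * (1.0 + sf)
    knee_range = (config.standing_knee_angle - config.seated_knee_angle) * (
        1.0 - 0.5 * sf
    )
    hip_range = (config.standing_hip_angle - config.seated_hip_angle) * (
        1.0 - 0.5 * sf
    )

    def jitter() -> float:
        return float(np.clip(1.0 + config.variability * rng.standard_normal(),
                             0.7, 1.3))

    k_sit, h_sit = config.seated_knee_angle, config.seated_hip_angle
    segments: list[tuple[float, float, float, float, float]] = []
    marks: list[tuple[float, float, float]] = []
    t = 0.0
    lead = 0.5 * config.hold_duration
    segments.append((lead, k_sit, k_sit, h_sit, h_sit))
    t += lead
    for _ in range(config.n_cycles):
        amp = jitter()
        k_std = min(k_sit + knee_range * amp, 180.0)
        h_std = min(h_sit + hip_range * amp, 180.0)
        up = trans * jitter()
        hold_up = config.hold_duration * jitter()
        down = trans * jitter()
        hold_down = config.hold_duration * jitter()
        rise_start = t
        segments.append((up, k_sit, k_std, h_sit, h_std))
        t += up
        stand_mid = t + 0.5 * hold_up
        segments.append((hold_up, k_std, k_std, h_std, h_std))
        t += hold_up
        segments.append((down, k_std, k_sit, h_std, h_sit))
        t += down
        descent_end = t
        segments.append((hold_down, k_sit, k_sit, h_sit, h_sit))
        t += hold_down
        marks.append((rise_start, stand_mid, descent_end))
    return segments, marks


def _sample_trajectories(segments, marks, config: SimulationConfig):
    """Sample knee/hip angle arrays on the frame grid from the segment list."""
    bounds = np.cumsum([0.0] + [seg[0] for seg in segments])
    total = bounds[-1]
    n_frames = int(math.floor(total * config.frame_rate))
    times = np.arange(n_frames) / config.frame_rate
    seg_idx = np.clip(np.searchsorted(bounds, times, side="right") - 1, 0,
                      len(segments) - 1)
    knee = np.empty(n_frames)
    hip = np.empty(n_frames)
    for i, (dur, k0, k1, h0, h1) in enumerate(segments):
        sel = seg_idx == i
        if not sel.any():
            continue
        u = (times[sel] - bounds[i]) / dur
        s = 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))
        knee[sel] = k0 + (k1 - k0) * s
        hip[sel] = h0 + (h1 - h0) * s
    if config.tremor_amplitude > 0:
        wobble = config.tremor_amplitude * np.sin(
            2.0 * np.pi * config.tremor_frequency * times
        )
        knee = np.clip(knee + wobble, 0.0, 180.0)
        hip = np.clip(hip + wobble, 0.0, 180.0)
    cycle_frames = [
        (
            int(math.floor(r * config.frame_rate)),
            min(int(math.floor(s * config.frame_rate)), n_frames - 1),
            min(int(math.floor(e * config.frame_rate)), n_frames - 1),
        )
        for r, s, e in marks
    ]
    return knee, hip, cycle_frames


def _pose_skeleton(knee: np.ndarray, hip: np.ndarray,
                   config: SimulationConfig) -> np.ndarray:
    """Forward-kinematics pose of the 17-joint skeleton, frames×17×3.

    Coordinates: x forward, y lateral, z up; the ankle is the fixed root and
    the shank stays vertical. All angle-bearing joints lie in the y=0 plane.
    """
    n = knee.shape[0]
    L = config.segment_lengths
    theta_k = np.radians(knee)
    theta_h = np.radians(hip)

    ankle = np.zeros((n, 3))
    knee_pos = ankle + np.array([0.0, 0.0, L["shank"]])
    gamma = np.pi - theta_k  # thigh deviation from vertical
    thigh_dir = np.stack(
        [-np.sin(gamma), np.zeros(n), np.cos(gamma)], axis=1
    )
    hip_pos = knee_pos + L["thigh"] * thigh_dir
    beta = theta_k - theta_h  # trunk deviation from vertical
    trunk_dir = np.stack([np.sin(beta), np.zeros(n), np.cos(beta)], axis=1)
    forward = np.stack([np.cos(beta), np.zeros(n), -np.sin(beta)], axis=1)

    pelvis = hip_pos
    spine = hip_pos + 0.5 * L["trunk"] * trunk_dir
    thorax = hip_pos + L["trunk"] * trunk_dir
    neck = hip_pos + 1.1 * L["trunk"] * trunk_dir
    head = hip_pos + 1.25 * L["trunk"] * trunk_dir

    def lateral(offset: float) -> np.ndarray:
        return np.array([0.0, offset, 0.0])

    # Arms folded across the chest, rigid in the trunk frame.
    coords = np.zeros((n, 17, 3))
    place = {
        "pelvis": pelvis,
        "right_hip": hip_pos,
        "right_knee": knee_pos,
        "right_ankle": ankle,
        "left_hip": hip_pos,
        "left_knee": knee_pos,
        "left_ankle": ankle,
        "spine": spine,
        "thorax": thorax,
        "neck": neck,
        "head": head,
        "left_shoulder": thorax + lateral(0.18),
        "left_elbow": thorax + 0.15 * forward + lateral(0.10),
        "left_wrist": thorax + 0.25 * forward + lateral(-0.05),
        "right_shoulder": thorax + lateral(-0.18),
        "right_elbow": thorax + 0.15 * forward + lateral(-0.10),
        "right_wrist": thorax + 0.25 * forward + lateral(0.05),
    }
    for name, traj in place.items():
        coords[:, H36M17.index(name), :] = traj
    return coords


def simulate_sts_recording(config: SimulationConfig | None = None) -> SimulatedRecording:
    """Generate one synthetic five-repetition sit-to-stand recording.

    Deterministic given ``config.seed``: the same configuration yields
    bit-identical keypoints, truth angles, and cycle marks.
    """
    config = config if config is not None else SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    segments, marks = _cycle_segments(config, rng)
    knee, hip, cycle_frames = _sample_trajectories(segments, marks, config)
    coords = _pose_skeleton(knee, hip, config)
    if config.keypoint_noise_sd > 0:
        coords = coords + rng.normal(0.0, config.keypoint_noise_sd, coords.shape)
    keypoints = KeypointSequence3D(
        coords=coords,
        scheme=H36M17,
        frame_rate=config.frame_rate,
        source_id=f"sim-seed{config.seed}",
    )
    truth = AngleSeries(
        values={
            "left_hip": hip.copy(),
            "right_hip": hip.copy(),
            "left_knee": knee.copy(),
            "right_knee": knee.copy(),
        },
        source_id=keypoints.source_id,
        frame_rate=config.frame_rate,
    )
    return SimulatedRecording(
        keypoints=keypoints,
        truth_angles=truth,
        truth_cycles=CycleSegmentation(boundaries=cycle_frames),
        config=config,
    )


#: stiffness_factor intervals by latent severity: monotone, gap >= 0.3.
_STIFFNESS_FACTOR_RANGE = {"mild": (0.05, 0.25), "severe": (0.55, 0.85)}
#: WOMAC integer score ranges by latent severity (stiffness 0-8, function 0-68).
_WOMAC_RANGES = {
    "mild": {"stiffness": (1, 3), "function": (1, 34)},
    "severe": {"stiffness": (4, 8), "function": (35, 68)},
}


def simulate_cohort(
    n_subjects: int,
    severity_mix: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    bilateral_prob: float = 0.5,
    target_length: int = TARGET_LENGTH,
) -> tuple[list[SubjectRecord], list[SimulatedRecording]]:
    """Generate a cohort of subjects with recordings, scores, and sides.

    Each subject gets a latent severity (``mild``/``severe`` in the exact
    proportions of ``severity_mix``), WOMAC stiffness and function scores
    drawn inside the defining intervals of that severity, a
    ``stiffness_factor`` monotone in the latent severity, affected side(s)
    with probability ``bilateral_prob`` of bilateral disease (else one side
    at random), and one simulated recording. The recording's noisy keypoints
    are run through angle extraction and length normalization to populate
    the subject's curve map — the same path real data takes.

    Raises
    ------
    CohortError
        Fewer than 2 subjects in a requested (nonzero-fraction) group.
    """
    if not math.isclose(sum(severity_mix), 1.0, abs_tol=1e-9):
        raise ConfigurationError("severity_mix fractions must sum to 1")
    n_mild = round(n_subjects * severity_mix[0])
    n_severe = n_subjects - n_mild
    for frac, count, label in (
        (severity_mix[0], n_mild, "mild"),
        (severity_mix[1], n_severe, "severe"),
    ):
        if frac > 0 and count < 2:
            raise CohortError(
                f"requested {label} group has {count} subject(s); need >= 2"
            )
    base = base_config if base_config is not None else SimulationConfig()
    rng = np.random.default_rng(seed)

    subjects: list[SubjectRecord] = []
    recordings: list[SimulatedRecording] = []
    labels = ["mild"] * n_mild + ["severe"] * n_severe
    for i, label in enumerate(labels):
        lo, hi = _STIFFNESS_FACTOR_RANGE[label]
        factor = float(rng.uniform(lo, hi))
        s_lo, s_hi = _WOMAC_RANGES[label]["stiffness"]
        f_lo, f_hi = _WOMAC_RANGES[label]["function"]
        stiffness_score = int(rng.integers(s_lo, s_hi + 1))
        function_score = int(rng.integers(f_lo, f_hi + 1))
        if rng.random() < bilateral_prob:
            sides = frozenset({"left", "right"})
        else:
            sides = frozenset({"left" if rng.random() < 0.5 else "right"})
        sub_seed = int(rng.integers(0, 2**31 - 1))
        config = replace(base, stiffness_factor=factor, seed=sub_seed)
        recording = simulate_sts_recording(config)
        angles = extract_angle_series(recording.keypoints)
        series = normalize_angle_series(angles, target=target_length)
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:03d}",
                womac_stiffness=stiffness_score,
                womac_function=function_score,
                affected_sides=sides,
                series=series,
            )
        )
        recordings.append(recording)
    return subjects, recordings


# H36M17 joint -> COCO17 joint for the sagittal orthographic projection.
_H36M_TO_COCO = {
    "left_shoulder": "left_shoulder",
    "right_shoulder": "right_shoulder",
    "left_elbow": "left_elbow",
    "right_elbow": "right_elbow",
    "left_wrist": "left_wrist",
    "right_wrist": "right_wrist",
    "left_hip": "left_hip",
    "right_hip": "right_hip",
    "left_knee": "left_knee",
    "right_knee": "right_knee",
    "left_ankle": "left_ankle",
    "right_ankle": "right_ankle",
}


def write_alphapose_projection(
    recording: SimulatedRecording,
    path: str | Path,
    pixels_per_unit: float = 400.0,
    image_origin: tuple[float, float] = (320.0, 700.0),
    confidence: float = 0.9,
) -> Path:
    """Write the recording as AlphaPose-style 2-D results JSON.

    The 3-D skeleton is projected orthographically onto the sagittal (x, z)
    plane and mapped to the 17-keypoint COCO layout; face keypoints, which
    the simulator does not model, are placed at small offsets from the head.
    Image y grows downward, as in pixel coordinates.
    """
    from .schemes import COCO17

    path = Path(path)
    ox, oy = image_origin
    coords = recording.keypoints.coords
    records = []
    for f in range(coords.shape[0]):
        kp = np.zeros((17, 3))
        head = coords[f, H36M17.index("head")]
        face = {
            "nose": (0.06, 0.0),
            "left_eye": (0.05, 0.03),
            "right_eye": (0.05, -0.03),
            "left_ear": (0.0, 0.06),
            "right_ear": (0.0, -0.06),
        }
        for name, (dx, dz) in face.items():
            idx = COCO17.index(name)
            kp[idx, 0] = ox + (head[0] + dx) * pixels_per_unit
            kp[idx, 1] = oy - (head[2] + dz) * pixels_per_unit
            kp[idx, 2] = confidence
        for src, dst in _H36M_TO_COCO.items():
            point = coords[f, H36M17.index(src)]
            idx = COCO17.index(dst)
            kp[idx, 0] = ox + point[0] * pixels_per_unit
            kp[idx, 1] = oy - point[2] * pixels_per_unit
            kp[idx, 2] = confidence
        records.append(
            {
                "image_id": f"{f}.jpg",
                "category_id": 1,
                "keypoints": [round(v, 4) for v in kp.ravel().tolist()],
                "score": 2.5,
            }
        )
    path.write_text(json.dumps(records))
    return path
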