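"""Readers and writers for pose-estimator keypoint files and angle-series CSV.

The pipeline's raw inputs are (a) 2-D image-plane keypoints in the AlphaPose
results-JSON dialect (one record per detection or per image, each with a flat
``keypoints`` array of x, y, score triples) and (b) 3-D keypoint sequences
from a video 2-D→3-D lifting step, stored as long-format CSV
(``frame,joint,x,y,z``) or as a NumPy ``.npy``/``.npz`` array of shape
frames × joints × 3.

Coordinates are kept in their native units throughout: with unconstrained
home recordings only joint *angles* are comparable across recordings, so no
rescaling is ever applied here.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import FormatError, GapError, ParseError, SchemeError
from .schemes import COCO17, H36M17, KeypointScheme, get_scheme

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .kinematics import AngleSeries

__all__ = [
    "KeypointSequence2D",
    "KeypointSequence3D",
    "read_alphapose_json",
    "read_keypoints3d",
    "write_keypoints3d",
    "interpolate_gaps",
    "write_angle_series_csv",
    "read_angle_series_csv",
]


@dataclass
class KeypointSequence2D:
    """Per-frame 2-D body-joint coordinates with detection confidences.

    Attributes
    ----------
    coords : ndarray, shape (frames, joints, 2)
        Image-plane positions in pixels.
    confidence : ndarray, shape (frames, joints)
        Per-keypoint detection scores in [0, 1].
    scheme : KeypointScheme
        Joint naming/ordering; defaults to the 17-keypoint COCO layout.
    frame_rate : float or None
        Frames per second, if known.
    """

    coords: np.ndarray
    confidence: np.ndarray
    scheme: KeypointScheme = COCO17
    frame_rate: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise FormatError(
                f"2-D coords must be frames×joints×2, got {self.coords.shape}"
            )
        if self.confidence.shape != self.coords.shape[:2]:
            raise FormatError("confidence shape must match coords frames×joints")
        if self.coords.shape[1] != self.scheme.n_joints:
            raise SchemeError(
                f"{self.coords.shape[1]} joints != scheme "
                f"{self.scheme.name!r} count {self.scheme.n_joints}"
            )
        if self.n_frames and (
            np.nanmin(self.confidence) < 0 or np.nanmax(self.confidence) > 1
        ):
            raise FormatError("confidences must lie in [0, 1]")
        bad = ~np.isfinite(self.coords).all(axis=2) & (self.confidence > 0)
        if bad.any():
            raise FormatError("non-finite coordinates with positive confidence")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]


@dataclass
class KeypointSequence3D:
    """Per-frame 3-D joint positions from the video-lifting step.

    Absolute scale is reconstruction-dependent and not meaningful across
    recordings; only angles derived from these coordinates are comparable.
    Missing values are carried as NaN until :func:`interpolate_gaps` resolves
    them.
    """

    coords: np.ndarray
    scheme: KeypointScheme = H36M17
    frame_rate: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(
                f"3-D coords must be frames×joints×3, got {self.coords.shape}"
            )
        if self.coords.shape[1] != self.scheme.n_joints:
            raise SchemeError(
                f"{self.coords.shape[1]} joints != scheme "
                f"{self.scheme.name!r} count {self.scheme.n_joints}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]

    @property
    def has_gaps(self) -> bool:
        return bool(np.isnan(self.coords).any())

    def joint(self, name: str) -> np.ndarray:
        """Trajectory of a named joint, shape (frames, 3)."""
        return self.coords[:, self.scheme.index(name), :]


def _frame_key(record: dict, position: int) -> tuple:
    """Sort key for AlphaPose records: numeric part of image id if present."""
    image_id = record.get("image_id", record.get("image_name"))
    if image_id is None:
        return (position,)
    digits = re.findall(r"\d+", str(image_id))
    return (int(digits[-1]),) if digits else (str(image_id),)


def read_alphapose_json(
    path: str | Path, scheme: str | KeypointScheme = COCO17
) -> KeypointSequence2D:
    """Read an AlphaPose-style results JSON into a 2-D keypoint sequence.

    Both dialects are accepted: a list with one record per image, or one
    record per detection. Records sharing an ``image_id`` are grouped and the
    highest-``score`` detection is kept, since the test protocol films a
    single subject.

    Raises
    ------
    ParseError
        Malformed JSON, or a record without a keypoints array.
    FormatError
        Keypoints array not divisible by 3 or joint count != scheme count.
    """
    path = Path(path)
    scheme = get_scheme(scheme)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(records, list):
        raise ParseError(f"{path}: expected a top-level list of records")

    best: dict[tuple, tuple[float, np.ndarray]] = {}
    for pos, rec in enumerate(records):
        if not isinstance(rec, dict) or "keypoints" not in rec:
            raise ParseError(f"{path}: record {pos} has no 'keypoints' array")
        flat = np.asarray(rec["keypoints"], dtype=float).ravel()
        if flat.size % 3 != 0:
            raise FormatError(
                f"{path}: record {pos} keypoints length {flat.size} "
                "not divisible by 3"
            )
        triples = flat.reshape(-1, 3)
        if triples.shape[0] != scheme.n_joints:
            raise FormatError(
                f"{path}: record {pos} has {triples.shape[0]} joints, "
                f"scheme {scheme.name!r} expects {scheme.n_joints}"
            )
        key = _frame_key(rec, pos)
        score = float(rec.get("score", 0.0))
        if key not in best or score > best[key][0]:
            best[key] = (score, triples)

    n = len(best)
    coords = np.zeros((n, scheme.n_joints, 2))
    conf = np.zeros((n, scheme.n_joints))
    for i, key in enumerate(sorted(best)):
        triples = best[key][1]
        coords[i] = triples[:, :2]
        conf[i] = np.clip(triples[:, 2], 0.0, 1.0)
    return KeypointSequence2D(
        coords=coords, confidence=conf, scheme=scheme, source_id=path.stem
    )


def read_keypoints3d(
    path: str | Path, scheme: str | KeypointScheme = H36M17
) -> KeypointSequence3D:
    """Read a 3-D keypoint sequence from CSV (``frame,joint,x,y,z``) or .npy/.npz.

    NaN coordinates are accepted and flagged as gaps for later interpolation.
    """
    path = Path(path)
    scheme = get_scheme(scheme)
    if path.suffix in (".npy", ".npz"):
        loaded = np.load(path)
        arr = loaded["coords"] if isinstance(loaded, np.lib.npyio.NpzFile) else loaded
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise FormatError(f"{path}: expected frames×joints×3, got {arr.shape}")
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
        required = {"frame", "joint", "x", "y", "z"}
        if not required.issubset(frame.columns):
            raise FormatError(
                f"{path}: CSV must have columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        n_frames = frame["frame"].nunique()
        n_joints = frame["joint"].nunique()
        if len(frame) != n_frames * n_joints:
            raise FormatError(f"{path}: ragged frame×joint table")
        frame = frame.sort_values(["frame", "joint"])
        arr = frame[["x", "y", "z"]].to_numpy(dtype=float).reshape(
            n_frames, n_joints, 3
        )
    if arr.shape[1] != scheme.n_joints:
        raise FormatError(
            f"{path}: {arr.shape[1]} joints under scheme {scheme.name!r} "
            f"expecting {scheme.n_joints}"
        )
    return KeypointSequence3D(coords=arr, scheme=scheme, source_id=path.stem)


def write_keypoints3d(seq: KeypointSequence3D, path: str | Path) -> Path:
    """Write a 3-D sequence as long-format CSV (``frame,joint,x,y,z``)."""
    path = Path(path)
    n_frames, n_joints, _ = seq.coords.shape
    frame_idx = np.repeat(np.arange(n_frames), n_joints)
    joint_idx = np.tile(np.arange(n_joints), n_frames)
    flat = seq.coords.reshape(-1, 3)
    pd.DataFrame(
        {
            "frame": frame_idx,
            "joint": joint_idx,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def _missing_mask(
    seq: KeypointSequence2D | KeypointSequence3D, min_confidence: float
) -> np.ndarray:
    """Boolean frames×joints mask of samples needing interpolation."""
    missing = ~np.isfinite(seq.coords).all(axis=2)
    if isinstance(seq, KeypointSequence2D):
        missing |= seq.confidence < min_confidence
    return missing


def interpolate_gaps(
    seq: KeypointSequence2D | KeypointSequence3D,
    max_gap: int = 5,
    min_confidence: float = 0.3,
):
    """Fill short runs of missing/low-confidence frames by linear interpolation.

    For each joint, a run of at most ``max_gap`` consecutive missing frames
    (NaN coordinates, or confidence below ``min_confidence`` for 2-D input)
    is replaced per-coordinate by the line between the flanking valid frames.
    Valid frames are returned bit-identical, which makes the operation
    idempotent. Longer runs, or runs touching the sequence boundary, raise
    :class:`~sitstand.errors.GapError`: they indicate the recording violated
    the protocol requirement to keep the whole body in view.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    missing = _missing_mask(seq, min_confidence)
    if not missing.any():
        return replace(seq)

    coords = seq.coords.copy()
    n_frames = seq.n_frames
    for j in range(seq.n_joints):
        col = missing[:, j]
        if not col.any():
            continue
        # Run boundaries of the missing mask for this joint.
        edges = np.flatnonzero(np.diff(np.concatenate(([0], col.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            run = stop - start
            if start == 0 or stop == n_frames:
                raise GapError(j, start, stop,
                               f"gap at joint {j} touches sequence boundary "
                               f"(frames {start}..{stop - 1})")
            if run > max_gap:
                raise GapError(j, start, stop,
                               f"gap of {run} frames at joint {j} exceeds "
                               f"max_gap={max_gap} (frames {start}..{stop - 1})")
            lo, hi = start - 1, stop  # flanking valid frames
            t = (np.arange(start, stop) - lo) / (hi - lo)
            coords[start:stop, j, :] = (
                coords[lo, j, :][None, :] * (1 - t[:, None])
                + coords[hi, j, :][None, :] * t[:, None]
            )

    out = replace(seq, coords=coords)
    if isinstance(out, KeypointSequence2D):
        # Interpolated samples get full confidence so the fill is idempotent.
        conf = out.confidence.copy()
        conf[missing] = 1.0
        out.confidence = conf
    return out


def write_angle_series_csv(series: "AngleSeries", path: str | Path) -> Path:
    """Write an angle series as CSV: one ``sample`` column plus one per site.

    Values are written at full float precision so that
    ``read_angle_series_csv(write_angle_series_csv(s)) == s``.
    """
    path = Path(path)
    data = {"sample": np.arange(series.length)}
    for site in series.sites:
        data[site] = series.values[site]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


def read_angle_series_csv(
    path: str | Path, required_sites: tuple[str, ...] | None = None
) -> "AngleSeries":
    """Read an angle-series CSV written by :func:`write_angle_series_csv`.

    ``required_sites`` makes absence of a site column a format error rather
    than a silently smaller series.
    """
    from .kinematics import SITES, AngleSeries  # deferred: import cycle

    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    site_cols = [c for c in frame.columns if c != "sample"]
    unknown = [c for c in site_cols if c not in SITES]
    if unknown:
        raise FormatError(f"{path}: unknown site column(s) {unknown}")
    if not site_cols:
        raise FormatError(f"{path}: no site columns found")
    if required_sites is not None:
        absent = [s for s in required_sites if s not in site_cols]
        if absent:
            raise FormatError(f"{path}: missing site column(s) {absent}")
    values = {site: frame[site].to_numpy(dtype=float) for site in site_cols}
    return AngleSeries(values=values, source_id=path.stem)
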