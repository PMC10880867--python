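"""Joint-angle extraction and sit-to-stand cycle segmentation.

The analysis tracks four sagittal extension–flexion angles — left/right hip
and left/right knee — through a five-repetition sit-to-stand test. Each angle
is the included angle at a vertex joint between the two adjacent body-segment
vectors, computed by the cosine rule

    theta = arccos( (a - v) . (b - v) / (|a - v| |b - v|) )

and expressed in degrees, so 180° is a fully extended joint. Because the
included angle is invariant to rigid motion and uniform scaling of the
keypoints, it is comparable across recordings made at arbitrary camera
angles and distances — the property that makes unconstrained home videos
usable at all.

Conventions
-----------
* knee angle: vertex at the knee, limbs toward the ipsilateral hip and ankle;
* hip angle: vertex at the hip, limbs toward a trunk reference joint
  (thorax, else spine, else the ipsilateral shoulder) and the ipsilateral
  knee. Trunk–thigh is the standard extension–flexion convention; which
  trunk joint anchors it is configurable via the site mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import AggregationError, DegenerateGeometryError, SchemeError
from .keypoint_io import KeypointSequence3D
from .schemes import KeypointScheme

__all__ = [
    "SITES",
    "AngleSeries",
    "CycleSegmentation",
    "joint_angle",
    "default_site_mapping",
    "extract_angle_series",
    "segment_cycles",
]

#: The four key sites, in canonical order.
SITES: tuple[str, ...] = ("left_hip", "right_hip", "left_knee", "right_knee")

#: site -> (limb-a joint, vertex joint, limb-b joint)
SiteMapping = dict[str, tuple[str, str, str]]


@dataclass
class AngleSeries:
    """Per-site joint-angle time series in degrees.

    All sites share one length; values lie in [0, 180] with no NaN (gaps
    must be interpolated upstream, in keypoint space).
    """

    values: dict[str, np.ndarray]
    source_id: str = ""
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("AngleSeries needs at least one site")
        unknown = [s for s in self.values if s not in SITES]
        if unknown:
            raise ValueError(f"unknown site label(s) {unknown}; expected {SITES}")
        self.values = {
            s: np.asarray(v, dtype=float)
            for s, v in self.values.items()
        }
        lengths = {v.shape[0] for v in self.values.values()}
        if len(lengths) != 1:
            raise ValueError(f"sites have mixed lengths {sorted(lengths)}")
        for s, v in self.values.items():
            if v.ndim != 1:
                raise ValueError(f"site {s!r} values must be 1-D")
            if v.size and (np.isnan(v).any() or v.min() < 0 or v.max() > 180):
                raise ValueError(f"site {s!r} has values outside [0, 180] or NaN")

    @property
    def sites(self) -> tuple[str, ...]:
        """Site labels in canonical order."""
        return tuple(s for s in SITES if s in self.values)

    @property
    def length(self) -> int:
        return next(iter(self.values.values())).shape[0]

    def __getitem__(self, site: str) -> np.ndarray:
        return self.values[site]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AngleSeries):
            return NotImplemented
        return self.sites == other.sites and all(
            np.array_equal(self.values[s], other.values[s]) for s in self.sites
        )


@dataclass
class CycleSegmentation:
    """Sit-to-stand cycles as (start, stand, end) sample triples.

    ``start``/``end`` are seated minima of the segmentation-site angle and
    ``stand`` the standing maximum between them; consecutive cycles may share
    a boundary sample (the subject sits once between two rises).
    """

    boundaries: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, stand, end in self.boundaries:
            if not (start <= stand <= end):
                raise ValueError(f"unordered cycle triple {(start, stand, end)}")
            if start < prev_end:
                raise ValueError("overlapping cycle intervals")
            prev_end = end

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries)


def joint_angle(a, vertex, b) -> float | np.ndarray:
    """Included angle at ``vertex`` between points ``a`` and ``b``, in degrees.

    Accepts single 3-D points or arrays of shape (..., 3); the angle is
    computed per leading index. The cosine argument is clipped to [-1, 1]
    before ``arccos`` so collinear points are numerically safe, and the
    result is clamped to [0, 180].

    Raises
    ------
    DegenerateGeometryError
        If either limb vector has zero length.
    """
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    degenerate = (nu == 0) | (nv == 0)
    if np.any(degenerate):
        frames = np.flatnonzero(np.atleast_1d(degenerate))
        raise DegenerateGeometryError(
            f"zero-length limb vector at index/frame {frames[:5].tolist()}"
        )
    cos = np.clip(np.sum(u * v, axis=-1) / (nu * nv), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos))
    theta = np.clip(theta, 0.0, 180.0)
    return float(theta) if theta.ndim == 0 else theta


def default_site_mapping(scheme: KeypointScheme) -> SiteMapping:
    """Build the standard site mapping for a scheme.

    Knees: (ipsilateral hip, knee, ipsilateral ankle).
    Hips: (trunk reference, hip, ipsilateral knee), with the trunk reference
    the first of thorax, spine, or ipsilateral shoulder present in the scheme.
    """
    mapping: SiteMapping = {}
    for side in ("left", "right"):
        hip, knee, ankle = f"{side}_hip", f"{side}_knee", f"{side}_ankle"
        for j in (hip, knee, ankle):
            if j not in scheme:
                raise SchemeError(
                    f"scheme {scheme.name!r} lacks joint {j!r} needed for "
                    "the default site mapping"
                )
        if "thorax" in scheme:
            trunk = "thorax"
        elif "spine" in scheme:
            trunk = "spine"
        elif f"{side}_shoulder" in scheme:
            trunk = f"{side}_shoulder"
        else:
            raise SchemeError(
                f"scheme {scheme.name!r} has no trunk reference "
                "(thorax/spine/shoulder)"
            )
        mapping[f"{side}_knee"] = (hip, knee, ankle)
        mapping[f"{side}_hip"] = (trunk, hip, knee)
    return mapping


def extract_angle_series(
    seq: KeypointSequence3D, mapping: SiteMapping | None = None
) -> AngleSeries:
    """Compute the four key-site angle series from a 3-D keypoint sequence.

    ``mapping`` overrides the per-site (limb-a, vertex, limb-b) joint names;
    by default :func:`default_site_mapping` of the sequence's scheme is used.

    Raises
    ------
    SchemeError
        A mapped joint name does not resolve in the sequence's scheme.
    DegenerateGeometryError
        Some frame has a zero-length limb vector (frame index reported).
    ValueError
        The sequence still contains NaN gaps.
    """
    if seq.has_gaps:
        raise ValueError(
            "sequence has NaN gaps; run interpolate_gaps before extraction"
        )
    mapping = mapping if mapping is not None else default_site_mapping(seq.scheme)
    values = {}
    for site, (a_name, v_name, b_name) in mapping.items():
        values[site] = joint_angle(
            seq.joint(a_name), seq.joint(v_name), seq.joint(b_name)
        )
    return AngleSeries(
        values=values, source_id=seq.source_id, frame_rate=seq.frame_rate
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge-shrunk windows (no phase shift)."""
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def segment_cycles(
    series: AngleSeries,
    site: str = "left_hip",
    smoothing_window: int = 9,
    min_prominence: float = 20.0,
) -> CycleSegmentation:
    """Segment sit-to-stand cycles from one site's angle signal.

    The signal is smoothed with a centered moving average, standing maxima
    are located as peaks with at least ``min_prominence`` degrees of
    prominence, and each cycle's seated start/end are the minima between
    neighbouring maxima (or the signal ends for the outermost cycles). A
    signal with no sufficiently prominent excursion yields zero cycles. The
    hip is the default segmentation site: hip excursions during a
    sit-to-stand are the most pronounced and give the cleanest extrema.
    """
    if site not in series.values:
        raise AggregationError(f"site {site!r} not present in series")
    x = series[site]
    if x.shape[0] <= 2 * smoothing_window:
        raise ValueError(
            f"series length {x.shape[0]} too short for smoothing window "
            f"{smoothing_window}"
        )
    smooth = _moving_average(x, smoothing_window)
    peaks, _ = find_peaks(smooth, prominence=min_prominence)
    if peaks.size == 0:
        return CycleSegmentation(boundaries=[])

    boundaries = []
    for k, stand in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else 0
        hi = peaks[k + 1] if k + 1 < peaks.size else smooth.shape[0] - 1
        start = lo + int(np.argmin(smooth[lo : stand + 1]))
        end = stand + int(np.argmin(smooth[stand : hi + 1]))
        boundaries.append((start, int(stand), end))
    return CycleSegmentation(boundaries=boundaries)
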