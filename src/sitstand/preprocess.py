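"""Length normalization and group-mean aggregation of angle curves.

Recordings differ in duration, so their angle series differ in sample count.
To compare subjects pointwise, every series is brought to a common length
(400 samples by default) by *evenly removing* samples: a series of length
n >= target keeps the samples at indices

    i_k = floor(k * n / target),   k = 0 .. target-1,

a strictly increasing subsequence that starts at index 0 and deletes the
n - target surplus samples at maximally even spacing. No resampling or
filtering touches the retained values, and the sample axis stays an index —
curves are never warped onto a common time or cycle-phase axis.

Series *shorter* than the target are a protocol anomaly; by default they
raise an error rather than being silently upsampled into a group mean. An
explicit ``policy="interpolate"`` opts in to linear upsampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import AggregationError, ShortSeriesError
from .kinematics import AngleSeries

__all__ = [
    "TARGET_LENGTH",
    "NormalizedSeries",
    "normalize_length",
    "normalize_angle_series",
    "mean_curve",
]

#: Common sample count every curve is normalized to.
TARGET_LENGTH: int = 400


@dataclass
class NormalizedSeries:
    """A length-normalized angle curve with its provenance.

    ``indices`` records which source samples were kept (for downsampled
    input) or is None for interpolated short input.
    """

    values: np.ndarray
    source_length: int
    site: str = ""
    source_id: str = ""
    indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def length(self) -> int:
        return self.values.shape[0]


def subsample_indices(n: int, target: int) -> np.ndarray:
    """Indices i_k = floor(k*n/target) kept when reducing length n to target."""
    k = np.arange(target)
    return (k * n) // target


def normalize_length(
    x,
    target: int = TARGET_LENGTH,
    policy: Literal["error", "interpolate"] = "error",
    site: str = "",
    source_id: str = "",
) -> NormalizedSeries:
    """Normalize a 1-D series to exactly ``target`` samples.

    For n >= target the output is the even-removal subsequence described in
    the module docstring (the identity when n == target). For n < target the
    default policy raises :class:`~sitstand.errors.ShortSeriesError`;
    ``policy="interpolate"`` linearly upsamples instead.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("input must be a non-empty 1-D series")
    if target < 2:
        raise ValueError("target must be >= 2")
    n = x.shape[0]
    if n >= target:
        idx = subsample_indices(n, target)
        return NormalizedSeries(
            values=x[idx], source_length=n, site=site,
            source_id=source_id, indices=idx,
        )
    if policy == "error":
        raise ShortSeriesError(n, target)
    if policy != "interpolate":
        raise ValueError(f"unknown short-series policy {policy!r}")
    new_pos = np.linspace(0, n - 1, target)
    return NormalizedSeries(
        values=np.interp(new_pos, np.arange(n), x),
        source_length=n, site=site, source_id=source_id, indices=None,
    )


def normalize_angle_series(
    series: AngleSeries,
    target: int = TARGET_LENGTH,
    policy: Literal["error", "interpolate"] = "error",
) -> dict[str, NormalizedSeries]:
    """Normalize every site of an angle series; returns site -> curve."""
    return {
        site: normalize_length(
            series[site], target=target, policy=policy,
            site=site, source_id=series.source_id,
        )
        for site in series.sites
    }


def mean_curve(curves: list[NormalizedSeries] | list[np.ndarray]) -> np.ndarray:
    """Pointwise arithmetic mean of equal-length normalized curves."""
    if not curves:
        raise AggregationError("cannot average an empty list of curves")
    arrays = [
        c.values if isinstance(c, NormalizedSeries) else np.asarray(c, dtype=float)
        for c in curves
    ]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise AggregationError(f"curves have mixed lengths {sorted(lengths)}")
    return np.mean(np.stack(arrays), axis=0)
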