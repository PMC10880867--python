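"""Keypoint scheme registry.

A *scheme* fixes the naming and ordering of body joints in a pose-estimator
output. Two 17-joint layouts are registered by default:

``coco17``
    The COCO whole-body layout emitted by 2-D pose estimators
    (nose, eyes, ears, shoulders, elbows, wrists, hips, knees, ankles).

``h36m17``
    The Human3.6M-style layout produced by video 2-D→3-D lifting models,
    with a pelvis root and explicit spine/thorax/neck/head trunk joints.

Users may register their own layout with :func:`register_scheme`; the
kinematics stage only requires that the scheme resolves the joint names it
is asked for (hips, knees, ankles, and a trunk reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SchemeError

__all__ = ["KeypointScheme", "register_scheme", "get_scheme", "COCO17", "H36M17"]


@dataclass(frozen=True)
class KeypointScheme:
    """An ordered mapping of joint names to array indices."""

    name: str
    joints: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.joints)) != len(self.joints):
            raise SchemeError(f"scheme {self.name!r} has duplicate joint names")
        object.__setattr__(
            self, "_index", {j: i for i, j in enumerate(self.joints)}
        )

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    def __contains__(self, joint: str) -> bool:
        return joint in self._index

    def index(self, joint: str) -> int:
        try:
            return self._index[joint]
        except KeyError:
            raise SchemeError(
                f"joint {joint!r} not in scheme {self.name!r} "
                f"(has: {', '.join(self.joints)})"
            ) from None


COCO17 = KeypointScheme(
    name="coco17",
    joints=(
        "nose",
        "left_eye",
        "right_eye",
        "left_ear",
        "right_ear",
        "left_shoulder",
        "right_shoulder",
        "left_elbow",
        "right_elbow",
        "left_wrist",
        "right_wrist",
        "left_hip",
        "right_hip",
        "left_knee",
        "right_knee",
        "left_ankle",
        "right_ankle",
    ),
)

H36M17 = KeypointScheme(
    name="h36m17",
    joints=(
        "pelvis",
        "right_hip",
        "right_knee",
        "right_ankle",
        "left_hip",
        "left_knee",
        "left_ankle",
        "spine",
        "thorax",
        "neck",
        "head",
        "left_shoulder",
        "left_elbow",
        "left_wrist",
        "right_shoulder",
        "right_elbow",
        "right_wrist",
    ),
)

_REGISTRY: dict[str, KeypointScheme] = {s.name: s for s in (COCO17, H36M17)}


def register_scheme(scheme: KeypointScheme, overwrite: bool = False) -> None:
    """Add a scheme to the registry so readers can resolve it by name."""
    if scheme.name in _REGISTRY and not overwrite:
        raise SchemeError(f"scheme {scheme.name!r} already registered")
    _REGISTRY[scheme.name] = scheme


def get_scheme(name: str | KeypointScheme) -> KeypointScheme:
    """Resolve a scheme by name; a scheme instance passes through unchanged."""
    if isinstance(name, KeypointScheme):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise SchemeError(
            f"unknown scheme {name!r} (registered: {sorted(_REGISTRY)})"
        ) from None
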