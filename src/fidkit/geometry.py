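"""Discrete mechanical model of the marker-wheel device.

The device carries four colour-coded marker wheels stacked on a common
rotation axis. Each wheel locks into one of ``positions_per_wheel`` discrete
stops (a Hirth-tooth coupling), ``angular_step_deg`` apart, and holds a
spherical fiducial at the end of an arm of wheel-specific length. Three
further spherical markers sit inside the axial column ("collector") and are
collinear by construction; they define the rotation axis in the image.

This module knows nothing about images or point clouds — it is the pure
combinatorial model: which wheels exist, how many stops each has, and the
full Cartesian product of stop choices (the configuration space searched by
:mod:`fidkit.search`).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

from .errors import GeometryError

#: Wheel order used everywhere: configuration tuples, CSV columns, CLI
#: output. Matches the device's stacking order blue, green, red, yellow.
DEFAULT_WHEEL_IDS = ("blue", "green", "red", "yellow")


@dataclass(frozen=True)
class DeviceGeometry:
    """Mechanical parameters of the marker-wheel device.

    Parameters
    ----------
    wheel_ids:
        Ordered labels of the wheels; the order is normative and fixes the
        meaning of every configuration tuple.
    positions_per_wheel:
        Number of discrete rotational stops per wheel.
    angular_step_deg:
        Angle between adjacent stops; ``positions_per_wheel *
        angular_step_deg`` must equal 360 exactly.
    arm_radii_mm:
        Perpendicular distance of each wheel's fiducial from the rotation
        axis. All radii must be strictly positive and pairwise distinct —
        the radii are what identifies a wheel in an unlabelled point cloud.
    collector_offsets_mm:
        Signed offsets of the three collinear column markers along the axis,
        relative to the device origin.
    """

    wheel_ids: tuple[str, ...] = DEFAULT_WHEEL_IDS
    positions_per_wheel: int = 10
    angular_step_deg: float = 36.0
    # Not printed device values: a plausible synthetic arm set covering a
    # large head circumference, one radius per wheel, pairwise distinct.
    arm_radii_mm: tuple[float, ...] = (60.0, 75.0, 90.0, 105.0)
    collector_offsets_mm: tuple[float, ...] = (0.0, 10.0, 20.0)

    def __post_init__(self) -> None:
        if len(self.wheel_ids) == 0:
            raise GeometryError("device needs at least one wheel")
        if len(set(self.wheel_ids)) != len(self.wheel_ids):
            raise GeometryError("wheel ids must be unique")
        if self.positions_per_wheel < 1:
            raise GeometryError("positions_per_wheel must be >= 1")
        if not math.isclose(
            self.positions_per_wheel * self.angular_step_deg, 360.0, abs_tol=1e-9
        ):
            raise GeometryError(
                f"positions_per_wheel ({self.positions_per_wheel}) x angular_step"
                f" ({self.angular_step_deg} deg) must equal 360 deg exactly"
            )
        if len(self.arm_radii_mm) != len(self.wheel_ids):
            raise GeometryError("need exactly one arm radius per wheel")
        if any(r <= 0 for r in self.arm_radii_mm):
            raise GeometryError("arm radii must be strictly positive")
        if len(self.collector_offsets_mm) != 3:
            raise GeometryError("exactly three collector marker offsets required")
        # NOTE: pairwise distinctness of the radii is checked by validate()
        # and by marker classification, not here, so that deliberately
        # malformed geometries can be constructed to exercise the ambiguity
        # error path.

    @property
    def n_wheels(self) -> int:
        return len(self.wheel_ids)

    @property
    def n_configurations(self) -> int:
        return self.positions_per_wheel ** self.n_wheels

    def validate(self) -> None:
        """Full validity check, including pairwise-distinct arm radii."""
        if len(set(self.arm_radii_mm)) != len(self.arm_radii_mm):
            raise GeometryError("arm radii must be pairwise distinct")

    def radius_of(self, wheel_id: str) -> float:
        return self.arm_radii_mm[self.wheel_ids.index(wheel_id)]

    # --- JSON interchange -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "wheels": list(self.wheel_ids),
            "positions_per_wheel": self.positions_per_wheel,
            "angular_step_deg": self.angular_step_deg,
            "arm_radii_mm": list(self.arm_radii_mm),
            "collector_offsets_mm": list(self.collector_offsets_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceGeometry":
        return cls(
            wheel_ids=tuple(d["wheels"]),
            positions_per_wheel=int(d["positions_per_wheel"]),
            angular_step_deg=float(d["angular_step_deg"]),
            arm_radii_mm=tuple(float(r) for r in d["arm_radii_mm"]),
            collector_offsets_mm=tuple(float(o) for o in d["collector_offsets_mm"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DeviceGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def default(cls) -> "DeviceGeometry":
        """The shipped default device (also available as packaged JSON)."""
        with resources.files("fidkit").joinpath("data/default_device.json").open() as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class WheelConfiguration:
    """One discrete stop index per wheel, 1-based; position 1 is home.

    ``indices`` is aligned with ``wheel_ids``; both are stored so a
    configuration is self-describing when serialized.
    """

    wheel_ids: tuple[str, ...]
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.wheel_ids) != len(self.indices):
            raise GeometryError("one position index per wheel required")

    def validate(self, geometry: DeviceGeometry) -> None:
        if self.wheel_ids != geometry.wheel_ids:
            raise GeometryError("configuration wheel order does not match geometry")
        for idx in self.indices:
            if not 1 <= idx <= geometry.positions_per_wheel:
                raise GeometryError(
                    f"position index {idx} outside [1, {geometry.positions_per_wheel}]"
                )

    def angle_deg(self, geometry: DeviceGeometry, wheel_id: str) -> float:
        """Rotation angle of ``wheel_id`` away from home for this configuration."""
        idx = self.indices[self.wheel_ids.index(wheel_id)]
        return (idx - 1) * geometry.angular_step_deg

    def label(self) -> str:
        """Human-readable form, e.g. ``'3, 6, 10, 4'`` in wheel order."""
        return ", ".join(str(i) for i in self.indices)

    @classmethod
    def home(cls, geometry: DeviceGeometry) -> "WheelConfiguration":
        return cls(geometry.wheel_ids, (1,) * geometry.n_wheels)


def enumerate_configurations(geometry: DeviceGeometry) -> list[WheelConfiguration]:
    """Enumerate the full configuration space of the device.

    Returns the Cartesian product of per-wheel stop indices in deterministic
    lexicographic order: the first wheel (blue) varies slowest, the last
    wheel (yellow) fastest. Length is ``positions_per_wheel ** n_wheels``
    (10 000 for the default device).
    """
    geometry.validate()
    rng = range(1, geometry.positions_per_wheel + 1)
    return [
        WheelConfiguration(geometry.wheel_ids, combo)
        for combo in itertools.product(rng, repeat=geometry.n_wheels)
    ]


def iter_configurations(geometry: DeviceGeometry) -> Iterator[WheelConfiguration]:
    """Lazy variant of :func:`enumerate_configurations`, same order."""
    geometry.validate()
    rng = range(1, geometry.positions_per_wheel + 1)
    for combo in itertools.product(rng, repeat=geometry.n_wheels):
        yield WheelConfiguration(geometry.wheel_ids, combo)
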