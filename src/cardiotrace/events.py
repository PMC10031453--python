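"""Core data containers shared across the package.

The sensor contract is simple: an optical mouse sensor reports integer
displacement *deltas* (counts) per polling interval along two axes. One count
corresponds to ``25.4 / dpi`` millimetres — at the reference 1600 DPI that is
0.015875 mm, i.e. the ~0.02 mm resolution of the recording hardware. A heart
preparation is pinned out along one axis, so only that axis carries signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import InputError, ParameterError

MM_PER_INCH = 25.4

__all__ = ["MM_PER_INCH", "DeviceSpec", "SensorEvent", "EventStream"]


@dataclass(frozen=True)
class DeviceSpec:
    """Optical sensor description.

    Parameters
    ----------
    dpi : int
        Sensor resolution in counts per inch. Higher DPI means finer
        displacement resolution (25.4/dpi mm per count).
    pinned_axis : {"x", "y"}
        Axis along which the preparation is pinned out; the contraction
        signal appears on this axis, the other axis stays at zero.
    sample_interval_ms : float
        Event emission (polling) interval in milliseconds.
    """

    dpi: int = 1600
    pinned_axis: str = "y"
    sample_interval_ms: float = 8.0

    def __post_init__(self) -> None:
        if not (isinstance(self.dpi, (int, np.integer)) and self.dpi > 0):
            raise ParameterError(f"dpi must be a positive integer, got {self.dpi!r}")
        if self.pinned_axis not in ("x", "y"):
            raise ParameterError(
                f"pinned_axis must be 'x' or 'y', got {self.pinned_axis!r}"
            )
        if not self.sample_interval_ms > 0:
            raise ParameterError(
                f"sample_interval_ms must be > 0, got {self.sample_interval_ms!r}"
            )

    @property
    def mm_per_count(self) -> float:
        return MM_PER_INCH / self.dpi


@dataclass(frozen=True)
class SensorEvent:
    """One sensor report: integer (dx, dy) displacement at time t_ms."""

    t_ms: int
    dx: int
    dy: int


def _as_int_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        rounded = np.asarray(values, dtype=float)
        if not np.all(rounded == np.rint(rounded)):
            raise InputError(f"{name} must contain integers")
        arr = rounded
    return arr.astype(np.int64)


@dataclass
class EventStream:
    """Ordered, timestamped delta events plus the device that produced them.

    Events are stored columnar (numpy int64 arrays) for speed; iterate to get
    :class:`SensorEvent` views.
    """

    device: DeviceSpec
    t_ms: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.t_ms = _as_int_array(self.t_ms, "t_ms")
        self.dx = _as_int_array(self.dx, "dx")
        self.dy = _as_int_array(self.dy, "dy")
        if not (len(self.t_ms) == len(self.dx) == len(self.dy)):
            raise InputError("t_ms, dx, dy must have equal lengths")

    def validate(self) -> None:
        """Raise :class:`InputError` at the first out-of-order timestamp."""
        if len(self.t_ms) > 1:
            bad = np.flatnonzero(np.diff(self.t_ms) < 0)
            if bad.size:
                i = int(bad[0]) + 1
                raise InputError(
                    f"timestamps not non-decreasing: event {i} has t_ms="
                    f"{int(self.t_ms[i])} < previous t_ms={int(self.t_ms[i - 1])}"
                )

    def __len__(self) -> int:
        return len(self.t_ms)

    def __iter__(self) -> Iterator[SensorEvent]:
        for t, dx, dy in zip(self.t_ms, self.dx, self.dy):
            yield SensorEvent(int(t), int(dx), int(dy))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.device == other.device
            and np.array_equal(self.t_ms, other.t_ms)
            and np.array_equal(self.dx, other.dx)
            and np.array_equal(self.dy, other.dy)
        )

    def pinned_deltas(self) -> np.ndarray:
        """Deltas along the device's pinned (signal-carrying) axis."""
        return self.dx if self.device.pinned_axis == "x" else self.dy

    def slice_span(self, t0_ms: float, t1_ms: float) -> "EventStream":
        """Events with ``t0_ms <= t_ms < t1_ms`` (half-open)."""
        mask = (self.t_ms >= t0_ms) & (self.t_ms < t1_ms)
        return replace(
            self, t_ms=self.t_ms[mask], dx=self.dx[mask], dy=self.dy[mask]
        )
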