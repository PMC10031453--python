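"""Reconstruction of position traces and windowed Max/Total summaries.

The sensor reports no absolute coordinates, only per-interval deltas; the
"actual position" is the running sum of those deltas (each delta is added to
the running value). Counts convert to millimetres as ``counts * 25.4 / dpi``.

Windowed summaries reproduce the four live display quantities — Max X,
Total X, Max Y, Total Y — over consecutive time windows: *Total* is the sum of
absolute deltas in the window (accumulated activity) and *Max* is the largest
single-event absolute delta. Absolute values make the summaries independent of
which direction along the axis the heart happens to pull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .events import MM_PER_INCH, DeviceSpec, EventStream

__all__ = [
    "PositionTrace",
    "WindowSummary",
    "accumulate",
    "counts_to_mm",
    "window_summaries",
]


@dataclass
class PositionTrace:
    """Cumulative sensor position over time, in counts and millimetres."""

    device: DeviceSpec
    t_ms: np.ndarray
    x_counts: np.ndarray
    y_counts: np.ndarray

    @property
    def x_mm(self) -> np.ndarray:
        return counts_to_mm(self.x_counts, self.device.dpi)

    @property
    def y_mm(self) -> np.ndarray:
        return counts_to_mm(self.y_counts, self.device.dpi)

    def pinned_counts(self) -> np.ndarray:
        return self.x_counts if self.device.pinned_axis == "x" else self.y_counts

    def pinned_mm(self) -> np.ndarray:
        return counts_to_mm(self.pinned_counts(), self.device.dpi)

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass(frozen=True)
class WindowSummary:
    """Max/Total activity of one time window, in counts and millimetres."""

    t0_ms: int
    t1_ms: int
    max_x: int
    total_x: int
    max_y: int
    total_y: int
    max_x_mm: float
    total_x_mm: float
    max_y_mm: float
    total_y_mm: float


def counts_to_mm(counts, dpi: float):
    """Convert sensor counts to millimetres: ``counts * 25.4 / dpi``.

    Linear and sign-preserving; accepts scalars or arrays. At 1600 DPI one
    count is 0.015875 mm (~0.02 mm sensor resolution).
    """
    if not dpi > 0:
        raise ParameterError(f"dpi must be > 0, got {dpi!r}")
    if np.isscalar(counts):
        return counts * MM_PER_INCH / dpi
    return np.asarray(counts) * MM_PER_INCH / dpi


def accumulate(stream: EventStream) -> PositionTrace:
    """Running sum of deltas per axis — the reconstructed position trace.

    Integer arithmetic throughout: counts are exact, and first-differencing
    the result reproduces the deltas. An empty stream yields an empty trace.
    Raises :class:`InputError` naming the first out-of-order timestamp.
    """
    stream.validate()
    return PositionTrace(
        device=stream.device,
        t_ms=stream.t_ms.copy(),
        x_counts=np.cumsum(stream.dx, dtype=np.int64),
        y_counts=np.cumsum(stream.dy, dtype=np.int64),
    )


def window_summaries(stream: EventStream, window_ms: float) -> list[WindowSummary]:
    """Per-window Max/Total activity along both axes.

    The recording span ``[t_first, t_last]`` is partitioned into consecutive
    half-open windows ``[t0, t0 + window_ms)``; events exactly at the final
    boundary fall into the last window. Empty windows report zeros.
    """
    if not window_ms > 0:
        raise ParameterError(f"window_ms must be > 0, got {window_ms!r}")
    stream.validate()
    if len(stream) == 0:
        return []

    t_first = int(stream.t_ms[0])
    t_last = int(stream.t_ms[-1])
    n_windows = max(1, int(np.ceil((t_last - t_first) / window_ms)))
    idx = ((stream.t_ms - t_first) // window_ms).astype(np.int64)
    idx = np.clip(idx, 0, n_windows - 1)

    adx = np.abs(stream.dx)
    ady = np.abs(stream.dy)
    total_x = np.bincount(idx, weights=adx, minlength=n_windows).astype(np.int64)
    total_y = np.bincount(idx, weights=ady, minlength=n_windows).astype(np.int64)
    max_x = np.zeros(n_windows, dtype=np.int64)
    max_y = np.zeros(n_windows, dtype=np.int64)
    np.maximum.at(max_x, idx, adx)
    np.maximum.at(max_y, idx, ady)

    mm = stream.device.mm_per_count
    out = []
    for w in range(n_windows):
        t0 = int(t_first + w * window_ms)
        t1 = int(t_first + (w + 1) * window_ms)
        out.append(
            WindowSummary(
                t0_ms=t0,
                t1_ms=t1,
                max_x=int(max_x[w]),
                total_x=int(total_x[w]),
                max_y=int(max_y[w]),
                total_y=int(total_y[w]),
                max_x_mm=float(max_x[w] * mm),
                total_x_mm=float(total_x[w] * mm),
                max_y_mm=float(max_y[w] * mm),
                total_y_mm=float(total_y[w] * mm),
            )
        )
    return out
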