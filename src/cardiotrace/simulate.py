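"""Synthetic contraction waveforms and the sensor quantizer.

This module stands in for the wet half of the recording rig: an isolated,
pinned-out snail heart beating over an optical mouse sensor. The heart of
*Lymnaea stagnalis* is two-chambered and myogenic; within each cardiac cycle
the auricle (A) contraction precedes the ventricle (V) contraction, giving the
characteristic biphasic displacement waveform. A cardioexcitatory drug such as
dopamine raises beat rate and contraction amplitude and slightly raises the
resting tone.

Model
-----
Displacement along the pinned axis is

    x(t) = tone + A * b((p - 0) / w) + V * b((p - lag) / w) + noise,

where ``p = t mod (1/rate)`` is the phase within the cycle, and ``b`` is a
raised-cosine bump, ``b(u) = (1 - cos(2*pi*u)) / 2`` on ``0 <= u < 1`` and 0
elsewhere: smooth, unimodal, compactly supported, returning exactly to
baseline. Gaussian noise of standard deviation ``noise_sd_mm`` is added to the
continuous displacement (physical jitter precedes quantization).

The quantizer converts the continuous trace into the sensor's native integer
delta events: it rounds the *absolute* position to counts at each polling
instant and emits differences, so the running sum of deltas reproduces the
rounded position exactly — zero drift by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError, ParameterError
from .events import MM_PER_INCH, DeviceSpec, EventStream

__all__ = [
    "WaveformParams",
    "DrugEffect",
    "ContinuousTrace",
    "DeviceSpec",
    "generate_waveform",
    "apply_drug",
    "quantize",
    "DOPAMINE_LIKE",
]


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of the biphasic contraction waveform.

    Defaults are sized to a ~2 mm organ: 0.8 Hz pacemaker, 0.3 mm auricle and
    1.0 mm ventricle pulses, 0.3 s A-to-V lag, 0.4 s pulse width, 0.5 mm
    resting tone. They are plausible-scale synthetic values, fully
    overridable, not measured constants.
    """

    rate_hz: float = 0.8
    auricle_amp_mm: float = 0.3
    ventricle_amp_mm: float = 1.0
    av_lag_s: float = 0.3
    pulse_width_s: float = 0.4
    tone_mm: float = 0.5
    noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.rate_hz) and self.rate_hz > 0):
            raise ParameterError(f"rate_hz must be > 0, got {self.rate_hz!r}")
        for name in ("auricle_amp_mm", "ventricle_amp_mm", "av_lag_s", "tone_mm",
                     "noise_sd_mm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
        if not (math.isfinite(self.pulse_width_s) and self.pulse_width_s > 0):
            raise ParameterError(
                f"pulse_width_s must be > 0, got {self.pulse_width_s!r}"
            )
        cycle = 1.0 / self.rate_hz
        if self.av_lag_s + self.pulse_width_s > cycle:
            raise ParameterError(
                "av_lag_s + pulse_width_s must not exceed the cycle length "
                f"1/rate_hz ({self.av_lag_s} + {self.pulse_width_s} > {cycle:g})"
            )


@dataclass(frozen=True)
class DrugEffect:
    """Multiplicative rate/amplitude modulation plus an additive tone shift."""

    rate_factor: float = 1.0
    amp_factor: float = 1.0
    tone_increment_mm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rate_factor", "amp_factor"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not math.isfinite(self.tone_increment_mm):
            raise ParameterError("tone_increment_mm must be finite")


#: Synthetic dopamine-like effect: rate x1.5, amplitude x1.5, tone +0.1 mm.
#: Chosen to land in the known cardioexcitatory regime (faster, stronger beats,
#: slightly raised tone); the magnitudes are invented, not measured.
DOPAMINE_LIKE = DrugEffect(rate_factor=1.5, amp_factor=1.5, tone_increment_mm=0.1)


@dataclass
class ContinuousTrace:
    """Continuous displacement trace: sample times (s) and position (mm)."""

    t_s: np.ndarray
    x_mm: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        if self.t_s.shape != self.x_mm.shape:
            raise InputError("t_s and x_mm must have equal lengths")
        if len(self.t_s) > 1 and not np.all(np.diff(self.t_s) > 0):
            raise InputError("t_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)


def _bump(u: np.ndarray) -> np.ndarray:
    # raised cosine on [0, 1), zero elsewhere
    out = np.zeros_like(u)
    mask = (u >= 0.0) & (u < 1.0)
    out[mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[mask]))
    return out


def generate_waveform(
    params: WaveformParams, duration_s: float, dt_s: float = 0.001
) -> ContinuousTrace:
    """Generate the biphasic displacement waveform.

    Each cycle holds an auricle pulse starting at cycle onset and a ventricle
    pulse starting ``av_lag_s`` later, both raised-cosine bumps of width
    ``pulse_width_s`` on top of the ``tone_mm`` baseline. With
    ``noise_sd_mm == 0`` the output is deterministic; otherwise the RNG is
    seeded from ``params.seed``.

    Returns a trace of ``ceil(duration_s / dt_s)`` samples.
    """
    if not duration_s > 0:
        raise ParameterError(f"duration_s must be > 0, got {duration_s!r}")
    if not dt_s > 0:
        raise ParameterError(f"dt_s must be > 0, got {dt_s!r}")

    n = math.ceil(duration_s / dt_s)
    t = np.arange(n) * dt_s
    phase = np.mod(t, 1.0 / params.rate_hz)
    x = np.full(n, params.tone_mm, dtype=float)
    if params.auricle_amp_mm > 0:
        x += params.auricle_amp_mm * _bump(phase / params.pulse_width_s)
    if params.ventricle_amp_mm > 0:
        x += params.ventricle_amp_mm * _bump(
            (phase - params.av_lag_s) / params.pulse_width_s
        )
    if params.noise_sd_mm > 0:
        rng = np.random.default_rng(params.seed)
        x += rng.normal(0.0, params.noise_sd_mm, size=n)
    return ContinuousTrace(t_s=t, x_mm=x)


def apply_drug(params: WaveformParams, effect: DrugEffect) -> WaveformParams:
    """Return new params with the drug effect applied; the input is unchanged.

    Rate is multiplied by ``rate_factor``, both pulse amplitudes by
    ``amp_factor``, and ``tone_increment_mm`` is added to the tone. Raises
    :class:`ParameterError` if the result violates the waveform invariants
    (e.g. a rate increase making the pulses spill into the next cycle).
    """
    return replace(
        params,
        rate_hz=params.rate_hz * effect.rate_factor,
        auricle_amp_mm=params.auricle_amp_mm * effect.amp_factor,
        ventricle_amp_mm=params.ventricle_amp_mm * effect.amp_factor,
        tone_mm=params.tone_mm + effect.tone_increment_mm,
    )


def quantize(trace: ContinuousTrace, device: DeviceSpec) -> EventStream:
    """Quantize a continuous trace into the sensor's integer delta events.

    The trace is resampled at ``device.sample_interval_ms``; at each polling
    instant the absolute position is rounded to integer counts
    (``round(x_mm * dpi / 25.4)``) and the emitted delta is the difference
    from the previous instant. The cumulative sum of deltas therefore equals
    the rounded position change from the trace start exactly (no drift). The
    off-pinned axis delta is always zero.
    """
    if len(trace) == 0:
        raise InputError("cannot quantize an empty trace")
    dt_s = device.sample_interval_ms / 1000.0
    t0 = float(trace.t_s[0])
    span = float(trace.t_s[-1]) - t0
    n_events = int(math.floor(span / dt_s + 1e-9))
    sample_t = t0 + np.arange(n_events + 1) * dt_s
    x = np.interp(sample_t, trace.t_s, trace.x_mm)
    pos_counts = np.rint(x * device.dpi / MM_PER_INCH).astype(np.int64)
    deltas = np.diff(pos_counts)
    t_ms = np.rint((sample_t[1:] - t0) * 1000.0).astype(np.int64)
    zeros = np.zeros_like(deltas)
    if device.pinned_axis == "x":
        dx, dy = deltas, zeros
    else:
        dx, dy = zeros, deltas
    return EventStream(device=device, t_ms=t_ms, dx=dx, dy=dy)
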