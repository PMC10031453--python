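"""Paired control-versus-treatment comparison.

The validation design: each preparation is recorded continuously — a control
epoch first, then the perfusate is switched to the drug solution, a wash-in
interval is discarded, and a treated epoch is recorded. Per-preparation total
distance in the two epochs gives paired samples, compared with a two-sided
paired Student t-test:

    d_i = treated_i - control_i,   t = mean(d) / (sd(d) / sqrt(n)),   df = n - 1

with the sample standard deviation (n-1 denominator). Significance stars
follow the usual convention: *** for p <= 0.001, ** for p <= 0.01, * for
p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analyze import BeatConfig, compute_metrics, detect_beats, label_av
from .errors import InputError
from .events import DeviceSpec, EventStream
from .reconstruct import accumulate
from .simulate import (
    ContinuousTrace,
    DrugEffect,
    WaveformParams,
    apply_drug,
    generate_waveform,
    quantize,
)

__all__ = ["Epochs", "PairedResult", "ValidationReport", "segment",
           "paired_ttest", "stars_for_p", "run_validation"]


@dataclass(frozen=True)
class Epochs:
    """Control and treated analysis windows (ms, half-open) of one recording."""

    control: tuple[int, int]
    treated: tuple[int, int]
    washin_ms: int = 0


@dataclass(frozen=True)
class PairedResult:
    """Paired t-test outcome with group summaries."""

    n: int
    t_stat: float
    df: int
    p_two_sided: float
    mean_control: float
    sd_control: float
    mean_treated: float
    sd_treated: float
    stars: str
    degenerate: bool = False


@dataclass
class ValidationReport:
    """Per-preparation metrics table plus the paired test on total distance."""

    result: PairedResult
    table: pd.DataFrame


def stars_for_p(p: float) -> str:
    """Significance stars with inclusive thresholds (*** at p <= 0.001)."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def segment(
    stream: EventStream,
    switch_t_ms: float,
    washin_ms: float,
    epoch_len_ms: float,
) -> Epochs:
    """Split a continuous recording around the perfusate switch.

    Control is the ``epoch_len_ms`` window ending at the switch; treated is
    the ``epoch_len_ms`` window starting ``washin_ms`` after it. Both are
    clipped to the recording; an empty epoch raises :class:`InputError`.
    """
    if not epoch_len_ms > 0:
        raise InputError(f"epoch_len_ms must be > 0, got {epoch_len_ms!r}")
    if washin_ms < 0:
        raise InputError(f"washin_ms must be >= 0, got {washin_ms!r}")
    stream.validate()
    if len(stream) == 0:
        raise InputError("cannot segment an empty recording")
    t_first = int(stream.t_ms[0])
    t_end = int(stream.t_ms[-1]) + 1
    if not (t_first <= switch_t_ms <= t_end):
        raise InputError(
            f"switch_t_ms={switch_t_ms!r} outside recording [{t_first}, {t_end})"
        )

    c0 = max(t_first, int(switch_t_ms - epoch_len_ms))
    c1 = int(switch_t_ms)
    r0 = int(switch_t_ms + washin_ms)
    r1 = min(t_end, int(switch_t_ms + washin_ms + epoch_len_ms))
    if c0 >= c1:
        raise InputError("control epoch falls outside the recording")
    if r0 >= r1:
        raise InputError("treated epoch falls outside the recording")
    return Epochs(control=(c0, c1), treated=(r0, r1), washin_ms=int(washin_ms))


def paired_ttest(
    control_vals: Sequence[float], treated_vals: Sequence[float]
) -> PairedResult:
    """Two-sided paired Student t-test on matched measurements.

    Requires n >= 2 pairs. If every difference is zero the statistic is
    undefined; the result is flagged degenerate with p = 1 and no stars.
    """
    c = np.asarray(control_vals, dtype=float)
    r = np.asarray(treated_vals, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise InputError("control and treated must be equal-length 1-d sequences")
    n = len(c)
    if n < 2:
        raise InputError(f"paired t-test needs n >= 2 pairs, got {n}")

    d = r - c
    summary = dict(
        n=n,
        df=n - 1,
        mean_control=float(c.mean()),
        sd_control=float(c.std(ddof=1)),
        mean_treated=float(r.mean()),
        sd_treated=float(r.std(ddof=1)),
    )
    if np.all(d == 0):
        return PairedResult(
            t_stat=float("nan"), p_two_sided=1.0, stars="", degenerate=True,
            **summary,
        )
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        # identical nonzero shift in every pair: evidence is unbounded
        t_stat = float(np.inf) if d.mean() > 0 else float(-np.inf)
        p = 0.0
    else:
        t_stat = float(d.mean() / (sd_d / np.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    return PairedResult(
        t_stat=t_stat, p_two_sided=p, stars=stars_for_p(p), **summary
    )


def _simulate_continuous_recording(
    base_params: WaveformParams,
    effect: DrugEffect,
    seed: int,
    epoch_s: float,
    washin_s: float,
    dt_s: float,
) -> ContinuousTrace:
    """One preparation's continuous recording: control epoch, then drug.

    The drugged waveform starts at the switch instant with independent noise;
    control and treated noise seeds are both derived from the preparation
    seed so the whole recording is reproducible from one integer.
    """
    c_seed, t_seed = (
        int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(2)
    )
    ctrl = generate_waveform(
        replace(base_params, seed=c_seed), duration_s=epoch_s, dt_s=dt_s
    )
    drugged = apply_drug(base_params, effect)
    treat = generate_waveform(
        replace(drugged, seed=t_seed), duration_s=washin_s + epoch_s, dt_s=dt_s
    )
    t = np.concatenate([ctrl.t_s, epoch_s + treat.t_s])
    x = np.concatenate([ctrl.x_mm, treat.x_mm])
    return ContinuousTrace(t_s=t, x_mm=x)


def run_validation(
    effect: DrugEffect,
    n_preps: int = 6,
    base_params: WaveformParams | None = None,
    seeds: Sequence[int] | None = None,
    epoch_s: float = 60.0,
    washin_s: float = 10.0,
    device: DeviceSpec | None = None,
    beat_config: BeatConfig = BeatConfig(),
    dt_s: float = 0.001,
) -> ValidationReport:
    """Run the full synthetic pharmacology validation experiment.

    For each preparation: simulate a continuous recording (control epoch with
    ``base_params``, then the drug-modified waveform after the switch),
    quantize it through the sensor model, segment into control/treated
    epochs discarding the wash-in, and compute per-epoch metrics. The paired
    t-test is then run on total distance across preparations. Fully
    reproducible given the per-preparation seeds.
    """
    if n_preps < 2:
        raise InputError(f"need at least 2 preparations, got {n_preps}")
    if base_params is None:
        base_params = WaveformParams(noise_sd_mm=0.05)
    if seeds is None:
        seeds = list(range(1, n_preps + 1))
    if len(seeds) != n_preps:
        raise InputError(
            f"need one seed per preparation: {len(seeds)} seeds for {n_preps}"
        )
    if device is None:
        device = DeviceSpec()

    rows = []
    for prep_id, seed in enumerate(seeds, start=1):
        trace = _simulate_continuous_recording(
            base_params, effect, int(seed), epoch_s, washin_s, dt_s
        )
        stream = quantize(trace, device)
        epochs = segment(
            stream,
            switch_t_ms=epoch_s * 1000.0,
            washin_ms=washin_s * 1000.0,
            epoch_len_ms=epoch_s * 1000.0,
        )
        pos = accumulate(stream)
        beats = label_av(detect_beats(pos, beat_config), base_params.rate_hz)
        m_ctrl = compute_metrics(stream, beats, span=epochs.control)
        m_treat = compute_metrics(stream, beats, span=epochs.treated)
        rows.append(
            {
                "prep_id": prep_id,
                "seed": int(seed),
                "control_total_distance_mm": m_ctrl.total_distance_mm,
                "treated_total_distance_mm": m_treat.total_distance_mm,
                "control_frequency_bpm": m_ctrl.frequency_bpm,
                "treated_frequency_bpm": m_treat.frequency_bpm,
                "control_mean_amplitude_mm": m_ctrl.mean_amplitude_mm,
                "treated_mean_amplitude_mm": m_treat.mean_amplitude_mm,
            }
        )
    table = pd.DataFrame(rows)
    result = paired_ttest(
        table["control_total_distance_mm"], table["treated_total_distance_mm"]
    )
    return ValidationReport(result=result, table=table)
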