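"""Waveform generator and sensor quantizer."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiotrace import (
    ContinuousTrace,
    DeviceSpec,
    DrugEffect,
    ParameterError,
    WaveformParams,
    apply_drug,
    generate_waveform,
    quantize,
)
from cardiotrace.events import MM_PER_INCH


def brute_force_peaks(x: np.ndarray, min_height: float) -> list[int]:
    """Independent local-maximum scan (no scipy)."""
    return [
        i
        for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] >= x[i + 1] and x[i] > min_height
    ]


class TestGenerateWaveform:
    def test_zero_amplitude_zero_tone_is_identically_zero(self):
        params = WaveformParams(
            auricle_amp_mm=0, ventricle_amp_mm=0, tone_mm=0, noise_sd_mm=0
        )
        trace = generate_waveform(params, duration_s=10.0)
        assert len(trace) == 10000
        assert np.all(trace.x_mm == 0.0)

    def test_cycle_count_matches_pacemaker_rate(self):
        # 0.5 Hz for 60 s must give exactly 30 ventricle peaks
        params = WaveformParams(rate_hz=0.5, noise_sd_mm=0.0)
        trace = generate_waveform(params, duration_s=60.0)
        # count only the dominant V peaks: well above tone + auricle pulse
        peaks = brute_force_peaks(trace.x_mm, params.tone_mm + 0.65)
        assert len(peaks) == 30

    def test_auricle_peak_precedes_larger_ventricle_peak_every_cycle(self):
        params = WaveformParams(
            rate_hz=0.8, auricle_amp_mm=0.3, ventricle_amp_mm=1.0, noise_sd_mm=0.0
        )
        dt = 0.001
        trace = generate_waveform(params, duration_s=30.0, dt_s=dt)
        cycle_n = int(round(1.0 / params.rate_hz / dt))
        n_cycles = len(trace) // cycle_n
        assert n_cycles == 24
        for k in range(n_cycles):
            seg = trace.x_mm[k * cycle_n : (k + 1) * cycle_n]
            peaks = brute_force_peaks(seg, params.tone_mm + 0.05)
            assert len(peaks) == 2, f"cycle {k}: expected A and V peaks"
            assert seg[peaks[0]] < seg[peaks[1]]  # earlier peak is the smaller

    def test_zero_noise_is_deterministic_and_seed_reproducible(self):
        p0 = WaveformParams(noise_sd_mm=0.0)
        a = generate_waveform(p0, 5.0)
        b = generate_waveform(p0, 5.0)
        assert np.array_equal(a.x_mm, b.x_mm)
        pn = WaveformParams(noise_sd_mm=0.05, seed=42)
        c = generate_waveform(pn, 5.0)
        d = generate_waveform(pn, 5.0)
        assert np.array_equal(c.x_mm, d.x_mm)
        e = generate_waveform(dataclasses.replace(pn, seed=43), 5.0)
        assert not np.array_equal(c.x_mm, e.x_mm)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(rate_hz=0.0), "rate_hz"),
            (dict(auricle_amp_mm=-0.1), "auricle_amp_mm"),
            (dict(pulse_width_s=0.0), "pulse_width_s"),
            (dict(rate_hz=2.0), "cycle length"),  # lag 0.3 + width 0.4 > 0.5
            (dict(noise_sd_mm=float("nan")), "noise_sd_mm"),
        ],
    )
    def test_invalid_params_raise_naming_the_constraint(self, kwargs, match):
        with pytest.raises(ParameterError, match=match):
            WaveformParams(**kwargs)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ParameterError, match="duration_s"):
            generate_waveform(WaveformParams(), duration_s=0.0)


class TestApplyDrug:
    def test_identity_effect_leaves_params_unchanged(self):
        p = WaveformParams()
        assert apply_drug(p, DrugEffect(1.0, 1.0, 0.0)) == p

    def test_arithmetic_and_input_immutability(self):
        p = WaveformParams(rate_hz=0.8, auricle_amp_mm=0.3, ventricle_amp_mm=1.0,
                           tone_mm=0.5)
        q = apply_drug(p, DrugEffect(1.5, 1.5, 0.1))
        assert q.rate_hz == pytest.approx(1.2)
        assert q.auricle_amp_mm == pytest.approx(0.45)
        assert q.ventricle_amp_mm == pytest.approx(1.5)
        assert q.tone_mm == pytest.approx(0.6)
        assert (q.av_lag_s, q.pulse_width_s, q.seed) == (p.av_lag_s,
                                                         p.pulse_width_s, p.seed)
        assert p.rate_hz == 0.8  # input untouched

    def test_effect_breaking_cycle_invariant_is_rejected(self):
        # rate x2 shrinks the cycle to 0.625 s < lag + width = 0.7 s
        with pytest.raises(ParameterError, match="cycle length"):
            apply_drug(WaveformParams(), DrugEffect(rate_factor=2.0))

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ParameterError, match="rate_factor"):
            DrugEffect(rate_factor=0.0)


class TestQuantize:
    def test_constant_trace_emits_all_zero_deltas(self, device):
        t = np.arange(0, 2.0, 0.001)
        trace = ContinuousTrace(t_s=t, x_mm=np.full_like(t, 1.234))
        stream = quantize(trace, device)
        assert len(stream) > 0
        assert np.all(stream.dx == 0) and np.all(stream.dy == 0)

    def test_one_inch_ramp_sums_to_dpi_counts(self, device):
        # linear ramp of exactly 25.4 mm at 1600 DPI -> 1600 counts total
        t = np.linspace(0.0, 10.0, 10001)
        trace = ContinuousTrace(t_s=t, x_mm=t / 10.0 * MM_PER_INCH)
        stream = quantize(trace, device)
        assert int(stream.pinned_deltas().sum()) == 1600

    def test_cumulative_deltas_match_direct_rounding_of_trace(self, device):
        params = WaveformParams(noise_sd_mm=0.05, seed=7)
        trace = generate_waveform(params, duration_s=20.0)
        stream = quantize(trace, device)
        sample_t = stream.t_ms / 1000.0
        x = np.interp(sample_t, trace.t_s, trace.x_mm)
        expected = np.rint(x * device.dpi / MM_PER_INCH) - np.rint(
            trace.x_mm[0] * device.dpi / MM_PER_INCH
        )
        assert np.array_equal(np.cumsum(stream.pinned_deltas()), expected)

    def test_off_axis_deltas_are_zero_and_axis_respected(self):
        trace = generate_waveform(WaveformParams(), duration_s=5.0)
        sx = quantize(trace, DeviceSpec(pinned_axis="x"))
        assert np.all(sx.dy == 0) and np.any(sx.dx != 0)

    def test_empty_trace_rejected(self, device):
        from cardiotrace import InputError

        with pytest.raises(InputError, match="empty"):
            quantize(ContinuousTrace(t_s=np.array([]), x_mm=np.array([])), device)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), dpi=st.sampled_from([400, 800, 1600, 3200]))
    def test_conservation_for_random_waveforms(self, seed, dpi):
        """Sum of deltas equals rounded endpoint minus rounded start, exactly."""
        rng = np.random.default_rng(seed)
        params = WaveformParams(
            rate_hz=float(rng.uniform(0.5, 1.2)),
            noise_sd_mm=float(rng.uniform(0.0, 0.2)),
            seed=seed,
        )
        trace = generate_waveform(params, duration_s=3.0)
        device = DeviceSpec(dpi=dpi)
        stream = quantize(trace, device)
        t_end_s = stream.t_ms[-1] / 1000.0
        x_end = np.interp(t_end_s, trace.t_s, trace.x_mm)
        expected = np.rint(x_end * dpi / MM_PER_INCH) - np.rint(
            trace.x_mm[0] * dpi / MM_PER_INCH
        )
        assert int(stream.pinned_deltas().sum()) == int(expected)


class TestDrugMonotonicity:
    @staticmethod
    def _path_length(params: WaveformParams) -> float:
        trace = generate_waveform(params, duration_s=30.0)
        return float(np.abs(np.diff(trace.x_mm)).sum())

    def test_path_length_nondecreasing_in_amp_and_rate_factor(self):
        base = WaveformParams(noise_sd_mm=0.0)
        amp_paths = [
            self._path_length(apply_drug(base, DrugEffect(amp_factor=f)))
            for f in (1.0, 1.25, 1.5)
        ]
        assert amp_paths == sorted(amp_paths)
        rate_paths = [
            self._path_length(apply_drug(base, DrugEffect(rate_factor=f)))
            for f in (1.0, 1.25, 1.5)
        ]
        assert rate_paths == sorted(rate_paths)
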