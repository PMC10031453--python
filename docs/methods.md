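# Methods

## The recording chain being modelled

An isolated, pinned-out heart beats above an optical mouse sensor. Pinning
stretches the muscle, which stimulates its myogenic pacemaker; the sensor
sees the refraction changes of the moving tissue as displacement and reports
integer counts per polling interval along two axes. The preparation is
pinned along one axis (the *pinned axis*), so one axis carries the signal
and the other stays at zero. One count is `25.4 / DPI` mm; at the reference
1600 DPI device that is 0.015875 mm, the ~0.02 mm resolution quoted for the
hardware. The software never sees absolute coordinates — only deltas — so
the position trace is reconstructed by running summation.

## Waveform model

Displacement along the pinned axis is

```
x(t) = tone + A·b(p/w) + V·b((p − lag)/w) + ε(t),   p = t mod (1/rate)
```

with `b(u) = (1 − cos 2πu)/2` on `0 ≤ u < 1`, zero elsewhere (raised
cosine). Each pacemaker cycle therefore contains an auricle pulse of
amplitude `A` at cycle onset and a ventricle pulse of amplitude `V` starting
`lag` seconds later — the biphasic A-then-V pattern of the two-chambered
heart. `ε` is i.i.d. Gaussian displacement noise added to the *continuous*
trace: physical jitter precedes quantization. The raised cosine was chosen
because it is smooth, unimodal, compactly supported, and returns exactly to
the baseline tone; any smooth unimodal pulse would serve, but the choice is
fixed and documented here.

Validity constraint: `lag + w ≤ 1/rate`, so the pulses of one cycle do not
spill into the next. Violations raise a parameter error naming the
constraint — including when a drug's rate factor shrinks the cycle below
the pulse envelope.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `rate_hz` | 0.8 | Hz | plausible resting rate for a small ectotherm heart |
| `auricle_amp_mm` | 0.3 | mm | smaller chamber, smaller pulse |
| `ventricle_amp_mm` | 1.0 | mm | dominant pulse, sized to a ~2 mm organ |
| `av_lag_s` | 0.3 | s | A precedes V by a fraction of the cycle |
| `pulse_width_s` | 0.4 | s | pulse occupies well under half a cycle |
| `tone_mm` | 0.5 | mm | nonzero diastolic baseline so tone shifts are visible |
| `noise_sd_mm` | 0 (0.05 in validation runs) | mm | a few counts of jitter at 1600 DPI |
| `dpi` | 1600 | counts/inch | the reference device |
| `sample_interval_ms` | 8 | ms | typical USB polling (~125 Hz) |

These are synthetic, plausible-scale values, not measurements; no printed
magnitudes exist for the real displacements. All are overridable.

The dopamine-like drug effect (rate ×1.5, amplitude ×1.5, tone +0.1 mm) is
likewise an invented effect size: the direction of each component (faster,
stronger, slightly raised tone) is the known cardioexcitatory profile, but
the magnitudes were chosen once as a clearly supra-threshold effect for the
synthetic validation and are not measured values.

## Quantizer

At each polling instant the absolute position is rounded to counts,
`round(x·dpi/25.4)`, and the emitted delta is the difference from the
previous instant. Rounding position-then-differencing (rather than rounding
per-interval velocity) makes the running sum of deltas equal the rounded
endpoint displacement exactly — zero accumulated drift, the conservation
property real optical sensors approximate. The continuous trace is linearly
interpolated at the polling instants before rounding.

## Reconstruction and windowed summaries

`accumulate` is exact integer summation; first-differencing it returns the
deltas bit-for-bit. Windowed summaries partition the recording into
consecutive half-open `[t0, t0 + window)` windows; per window and axis,
**Total** = Σ|delta| and **Max** = max single-event |delta|. Two genuinely
open readings existed for the live display's "Max": largest single delta
versus largest cumulative excursion within the window; the per-event reading
was adopted because it shares the delta semantics of the displayed bars and
makes window totals exactly re-chunkable (any partition of the recording
sums to the same whole-stream Σ|delta|). Absolute values make every summary
independent of the arbitrary sign convention of the pinned axis. An event
falling exactly on the final window boundary is counted in the last window.

## Beat detection and A/V labelling

The pinned-axis mm trace is smoothed with a centred moving average
(`smoothing_ms`, default 50 ms — small against the 400 ms pulse), then local
maxima with prominence ≥ `min_prominence_mm` (default 0.1 mm — far above
the 0.016 mm quantization step, far below a ~1 mm pulse) and spacing ≥
`refractory_ms` (default 200 ms — keeps both A and V peaks of a cycle) are
taken as beats. Amplitude is peak minus the minimum between the previous
peak (or trace start) and this peak: peak-minus-preceding-trough, so a slow
tone drift — precisely what a cardioexcitatory drug produces — does not leak
into amplitude.

Labelling pairs consecutive peaks closer than 0.75 of the hinted pacemaker
cycle: earlier = A, later = V; unpaired peaks are labelled V. The 0.75
fraction (rather than a full cycle) is deliberate: within-cycle A–V spacing
is a small fraction of the cycle while successive lone beats sit a full
cycle apart, and the sub-cycle window keeps single-pulse trains correctly
unpaired even when polling quantizes peak times by a few milliseconds.
Labelling is best-effort; under heavy noise an extra or missed peak can
shift the pairing within a stretch of the recording.

Frequency counts only V-labelled or unlabelled beats, so a biphasic A+V
cycle counts once — the physiological heart rate. **Total distance** is
Σ|delta| over the analysis span converted to mm: the single metric that
grows with both beat amplitude and beat frequency. Whether such a metric
should be normalised per unit time is ambiguous when spans are unequal, so
a per-minute value is reported alongside the raw one; the paired experiment
uses equal spans, where the two are equivalent.

## Paired comparison

Each preparation is one continuous recording: a control epoch, the
perfusate switch, a discarded wash-in interval (default 10 s), then the
treated epoch (default epochs 60 s). In the simulator the drug-modified
waveform starts at the switch instant with an independently seeded noise
stream; both sub-seeds derive from the preparation seed, so every recording
is reproducible from one integer.

Per-preparation total distance in the two epochs gives paired samples;
the test is the two-sided paired Student t-test with sample SD
(n−1 denominator) and `df = n − 1`. Sidedness is two-sided as the
conservative default. Stars use inclusive thresholds (\*\*\* at p ≤ 0.001).
Degenerate input (every difference exactly zero) yields an undefined t,
reported as p = 1 with no stars and a `degenerate` flag; an exactly
constant nonzero shift (sd(d) = 0) is reported as infinite t with p = 0.
The t tail probability is evaluated with the Student-t survival function;
the test suite checks it against an independent
regularised-incomplete-beta evaluation and against a reference paired-test
implementation.

## What the synthetic generator does and does not capture

It reproduces: the biphasic A-then-V cycle, delta-event quantization at
arbitrary DPI and polling rate, displacement noise, tone shifts, and the
paired continuous-recording design. It does not capture: beat-to-beat rate
variability (the pacemaker is strictly periodic), arrhythmias, gradual
drug wash-in kinetics (the effect switches instantaneously at the
perfusate switch), 2-D motion (the off-axis delta is identically zero), or
sensor imperfections other than quantization (no dropout, no nonlinearity).
Passing tests therefore demonstrate that the processing chain is correct
and sensitive under these idealised conditions, not that real recordings of
any particular tissue will show a given effect size.

## Numerical and design notes

- Problem sizes: validation runs simulate at 1 ms waveform resolution and
  8 ms polling; the null-distribution Monte-Carlo study (200 replicates of
  the identity-effect experiment) uses 8 s epochs at 2 ms resolution — the
  type-I-error property being checked is epoch-length invariant, and the
  shorter epochs keep the study quick.
- Timestamps are integer milliseconds; all spans and windows are half-open
  `[t0, t1)` to avoid double counting.
- The native `.drec` format is JSON-lines, UTF-8, LF newlines: one header
  object (format version, DPI, pinned axis, polling interval, creation
  time, optional simulation provenance) then one event object per line.
  CSV export carries deltas as the authoritative columns; position and mm
  columns are derived. XLS export is deliberately out of scope — CSV is the
  canonical interchange format.
- Known limitations: A/V labelling is greedy and can mis-pair after a
  missed or spurious peak in noisy data; beat detection assumes the
  contraction signal dominates the pinned axis; the simulator's effect
  sizes are synthetic, so the validation experiment demonstrates pipeline
  sensitivity, not a measured pharmacological magnitude.
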