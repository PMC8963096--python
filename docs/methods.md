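# Methods

## Signal model

A reflectance PPG photocurrent for wavelength *w* is synthesized as

```
i_w(t) = DC_w · (1 + m_b sin 2π f_r t)
       + (DC_w · PI_w / 100) · p(t) · (1 + m_a sin 2π f_r t)
       + ε(t) + A_m sin 2π f_m t
```

* `DC_w` — quasi-static baseline photocurrent in microamps, in (0, 1] (the
  order of magnitude a PPG photodiode delivers). Defaults: 1.0 µA for red
  and IR.
* `PI_w` — perfusion index in percent, in [0, 20]: the clean AC peak
  amplitude is exactly `DC_w · PI_w / 100` because the per-beat pulse
  template `p(t)` is normalized to min 0, max 1. The IR channel defaults to
  a larger PI (4.25%) than red (1.75%), matching the stronger infrared
  pulsation of perfused tissue; their ratio 7/17 corresponds to SpO2 = 97%
  under the default calibration.
* `p(t)` — a pulse train whose beats start at intervals of 60/HR seconds
  (optionally jittered by a multiplicative Gaussian factor, truncated at
  ±3σ). Each beat is the sum of two Gaussian bumps — a systolic wave
  (center 0.15 s, σ 0.05 s) and a smaller dicrotic wave (center 0.40 s,
  σ 0.08 s) — renormalized per beat. A two-bump log-concave template is the
  simplest shape with identifiable systolic and diastolic waves; no claim is
  made that it reproduces any particular morphology database.
* Respiration enters twice, each with its own depth: baseline wander `m_b`
  (default 1% of DC) and AC amplitude modulation `m_a` (default 10% of AC).
* `ε(t)` — additive white Gaussian noise on the photocurrent; optional mains
  sinusoid `A_m` at `f_m` (default 50 Hz). Motion artifacts and skin-optics
  (Beer–Lambert) modelling are deliberately out of scope.

All randomness flows from the single integer seed of `PhysioGroundTruth`
through `numpy.random.default_rng([seed, stream])`, one stream for the beat
schedule and one per wavelength for noise, so identical configurations are
byte-identical and channels share one heartbeat.

LED time multiplexing is modelled at the frame level: each multiplexing
frame emits one mid-pulse sample per channel in schedule order, so
`demultiplex(multiplex(...))` is lossless by construction. The LED switching
frequency is configurable (default 1 kHz) since only its order of magnitude
is fixed by hardware practice; it must be at least twice the per-channel
sample rate.

### What the generator does not emulate

Real PPG contains motion artifacts, ambient-light transients, vasomotor and
sympathetic baseline dynamics, and beat-morphology variability none of which
are modelled here. Passing tests therefore demonstrate algorithmic
correctness on signals with known ground truth — recovery of planted rates
and amplitudes, filter responses matching analytic forms — not clinical
performance on recorded data.

## Analog front end

Stages operate about a virtual ground VG = supply/2 (1.65 V at 3.3 V) and
saturate at the rails, mirroring single-supply op-amp behavior:

* TIA: `v = VG + polarity · i · R_f` (polarity is a configuration flag; the
  chain's inverting amplifier flips the waveform downstream).
* RC stages: the continuous first-order transfer function (`ω_c/(s+ω_c)`
  low-pass, `s/(s+ω_c)` high-pass) discretized by the **bilinear transform**
  at the trace rate, chosen because it maps DC and Nyquist gains of
  first-order sections exactly. The stage filters the deviation from VG, so
  the operating point never shifts. A corner undersampled below fs < 20 f_c
  warns and proceeds. Corner frequencies may be given directly (from a
  filter's band label) or derived from components via `f_c = 1/(2πRC)`; the
  0.5 Hz high-pass corner is taken from the band label by default because
  the canonical component pairing (1 MΩ, 1 µF) yields 0.159 Hz, not 0.5 Hz.
* Inverting amplifier: `v = VG − G (v_in − VG)`, clipped.
* ADC: nearest-sample decimation (the analog low-pass ahead of it acts as
  the anti-alias filter, as on a board), then uniform quantization of
  [0, supply] into 2^bits codes with **round-half-away-from-zero** on the
  code scale — pinned so mid-supply on a 12-bit converter is code 2048.

## FIR design

The reference band-pass: 396 taps at fs = 100 Hz, passband 0.5–5 Hz (or
0.5–10 Hz), transition bands 0.5 Hz **centered on the printed cutoffs**
(stop band ends at f_c − 0.25 Hz, passband starts at f_c + 0.25 Hz).
Equiripple (Parks–McClellan via `scipy.signal.remez`) with band weights
(stop1, pass, stop2) = (10, 1, 100). The 10× stop2:stop1 ratio buys the
~20 dB extra attenuation of the second stop band; de-weighting the passband
10× relative to the first stop band is what makes 40/60 dB reachable at this
tap count and transition width — the achieved design measures ≈ 42/62 dB
with ±0.7 dB passband ripple (within the ±1 dB passband-unity contract).
Even-length symmetric coefficients give exact linear phase with group delay
(N−1)/2 = 197.5 samples; delay compensation (on by default in analysis
pipelines, off for raw CLI filtering) advances the output by ⌊(N−1)/2⌋.

The hybrid mode applies the digital FIR low-pass to a tap recorded after
the analog first-order high-pass: gentler phase distortion near the lower
band edge preserves the systolic/dicrotic two-wave morphology at least as
well as the sharp full-digital band-pass (tested as mean per-beat count of
local maxima).

## Beat detection

Candidate peaks are local maxima of a lightly smoothed signal (moving
average, default 0.1 s) above an adaptive threshold `MA + α·A`, with MA a
0.75 s moving average, A the rolling standard deviation of the residual over
the same window, and α = 1 by default. Peaks closer than 0.25 s are merged
(the taller wins). A candidate is **rejected as premature** when its
interval from the last accepted peak is more than 30% shorter than the
median candidate interval — this removes artifactual spikes between beats —
while an over-long interval re-synchronizes instead of cascading rejections,
and the interval itself is excluded from the IBI pool. Valleys are signal
minima between consecutive accepted peaks, plus one before the first and
one after the last, so every accepted peak is bracketed. Heart rate is
`60000 / mean(IBI in ms)`.

## Valley-line AC/DC and SpO2

Default projection is **vertical**: DC is the valley-to-valley chord
evaluated at the peak's time; AC is the peak height above it. The
perpendicular variant (foot of the perpendicular from the peak to the
chord) is provided but is unit-dependent, so axes are rescaled by the
beat's amplitude/time spans first; on a horizontal chord both coincide.
Per-channel aggregates are means over beats; one R per analysis window
(default 40 s, non-overlapping) from window-averaged AC/DC, and per-window
SpO2 values are averaged.

Time-domain SpO2 pre-smooths both channels with the same 0.1 s moving
average. Any identical linear filter scales both channels' AC by the same
factor (they share the pulse template), so R is invariant while peak/valley
noise bias shrinks.

The curvilinear calibration `104 − 17 R` exceeds 100% for R < 4/17; results
are clamped to [0, 100] and the clamp is logged. The built-in lookup table
is sampled from the curvilinear map on R ∈ {0.20, 0.25, …, 1.20} (vendor
tables are proprietary); any strictly monotone two-column table can be
loaded instead. A linear `K·R` mode is provided; no default K is asserted
because K is a device calibration constant.

Known residual: respiratory baseline wander curves the signal between
valleys, and the straight valley line then mis-attributes a small, equal
absolute amount to both channels' AC. With the default 1% wander this moves
SpO2 by ≈ 0.4 points at R ≈ 0.4 — visible in the worked example (97.38%
instead of 97.00%) and well inside the ±1-point recovery contract.

## Amplitude spectrum

Segments of 310 samples (default), Hamming-windowed, 93.54% overlap
(hop = 20 at 310), zero-padded to ≥ 4096 points; magnitudes averaged and
divided by the window sum so a sinusoid of amplitude A reads A at its bin.
Two numerical choices matter at these operating points:

* **Analytic-signal (one-sided) spectrum.** A 310-sample window at 125 Hz
  spans 2.48 s — the Hamming mainlobe (± 0.81 Hz) is four times wider than a
  0.195 Hz respiratory component, so in a real-FFT spectrum the negative-
  frequency image overlaps the positive one and drags the respiratory argmax
  to the search-band edge. Computing the spectrum of the Hilbert analytic
  signal removes the image; the respiratory peak then localizes within one
  zero-padded bin (0.0305 Hz) of the truth.
* **Global mean removal.** The DC level (three orders of magnitude above the
  respiratory amplitude) is subtracted before windowing — over the full
  trace, not per segment, so the subtraction does not nibble at the
  respiratory component itself. The removed mean is reported as `dc_level`
  and re-inserted at the 0 Hz bin.

Peak search bands default to 0.1–0.5 Hz (respiratory) and 0.7–3.5 Hz
(cardiac). The respiratory peak is flagged low-confidence below 10% of the
cardiac amplitude (pure window leakage sits well under that; genuine
respiratory baseline power sits above it). The frequency-domain SpO2 uses
the cardiac-peak amplitude as AC and, following the spectral-ratio
convention, the respiratory-peak amplitude as DC; `dc_source="zero_bin"`
substitutes the physical DC level, which is the mode quantitative recovery
tests use, since the respiratory-peak amplitude depends on the (arbitrary)
wander depth.

## Problem sizes and defaults used in validation

Validation runs use 40–120 s of signal at 125 Hz (5 000–15 000 samples),
60 s for heart-rate recovery across 50–120 bpm, and 16 384-point response
grids for filter measurements; these sizes make every planted quantity
recoverable at its stated tolerance while keeping the whole suite fast.
The `spo2_97` scenario's "mild" noise is σ = 0.1% of the DC level (~6% of
the red AC amplitude), a quiet-front-end noise floor.

## Limitations

* The generator's beat template is stylized; morphology-sensitive metrics
  (augmentation index, pulse-wave analysis) should not be benchmarked on it.
* The front-end model omits op-amp non-idealities (offset, bandwidth,
  noise), ambient-light cancellation and DC-tracking hardware.
* The frequency-domain SpO2's respiratory-peak DC convention ties R to the
  respiratory modulation depth; it agrees with the time-domain method only
  when wander depths match across channels (they do here by construction).
* IIR/adaptive/wavelet filtering is out of scope.
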