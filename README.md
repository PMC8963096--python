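# ppgkit

An in-silico photoplethysmography (PPG) signal chain for teaching, testing
and benchmarking pulse-oximetry algorithms. The package reproduces, entirely
in software, what a reflectance pulse-oximeter front end does to the light
reflected from perfused tissue:

1. **`ppgkit.physio`** — a synthetic multi-wavelength PPG photocurrent
   generator with planted ground truth: a pulsatile AC component (two-bump
   systolic + dicrotic beat template) riding on a large quasi-static DC
   baseline, respiratory baseline wander and amplitude modulation,
   per-wavelength perfusion index, white noise, optional mains interference,
   seeded beat-interval jitter, and red/IR LED time multiplexing with
   mid-pulse sampling.
2. **`ppgkit.frontend`** — a discrete-time model of a single-supply (3.3 V)
   analog front end: transimpedance amplifier, two first-order RC filter
   stages (bilinear-transform discretization), inverting amplifier about the
   1.65 V virtual ground, rail clipping, and an ADC — with a tap after every
   stage, like the test points of a lab board.
3. **`ppgkit.filters`** — Parks–McClellan equiripple FIR band-pass design
   (the reference design: 396 taps at 100 Hz, 0.5–5 Hz passband, 0.5 Hz
   transitions, ≥ 40 dB / ≥ 60 dB stop bands) plus a hybrid mode: analog
   high-pass followed by a digital FIR low-pass.
4. **`ppgkit.vitals`** — beat segmentation (adaptive threshold + inter-beat
   interval rejection), heart rate, valley-line AC/DC and perfusion-index
   estimation, and SpO2 by three methods: time-domain with the curvilinear
   calibration, time-domain with a lookup table, and frequency-domain from
   an averaged short-window amplitude spectrum.
5. **`ppgkit.io` / `ppgkit.cli` / `ppgkit.fixtures`** — CSV trace and YAML
   config I/O, a `ppgkit` command line, and named reproducible scenarios.

## The statistic at the core

Pulse oximetry rests on the **ratio of ratios**

```
R = (AC/DC)_red / (AC/DC)_IR
```

where AC and DC are the pulsatile and baseline amplitudes of the PPG at the
red (~660 nm) and infrared (~940 nm) wavelengths. Oxygenated and
deoxygenated haemoglobin absorb these wavelengths differently, so R predicts
the arterial oxygen saturation. The default calibration is the curvilinear
map

```
SpO2 = 104 − 17 R        (clamped to [0, 100] %)
```

with a linear `K·R` mode and user-supplied lookup tables as alternatives.
In the time domain, AC/DC comes from the valley-line construction (a
straight line between the two valleys bracketing a systolic peak gives DC;
the peak height above that line is AC). In the frequency domain, the
cardiac and respiratory peaks of an averaged Hamming-windowed amplitude
spectrum play the roles of AC and DC.

## Worked example

```python
import ppgkit as pk
from ppgkit.fixtures import spo2_97_ground_truth

# red/IR pair with perfusion indices 1.75% / 4.25%  ->  R = 7/17, SpO2 = 97%
gt = spo2_97_ground_truth(seed=1)
red, ir = pk.synthesize_pair(gt, sample_rate_hz=125.0)

res = pk.spo2_time_domain(red.samples, ir.samples, 125.0, window_s=40.0)
print(f"R = {res.r_value:.4f}, SpO2 = {res.spo2_percent:.2f} %")

seg = pk.detect_beats(ir)
print(f"HR = {pk.compute_hr(seg):.1f} bpm "
      f"({seg.n_accepted} beats accepted, {seg.n_rejected} rejected)")
```

prints

```
R = 0.3896, SpO2 = 97.38 %
HR = 75.0 bpm (50 beats accepted, 0 rejected)
```

The planted saturation is 97%: the pipeline recovers it to a fraction of a
percentage point; the small deviation of R from 7/17 ≈ 0.4118 comes from
respiratory baseline wander crossing the valley-line construction (see
`docs/methods.md`). The same pair through the frequency-domain method:

```python
print(pk.spo2_frequency_domain(red.samples, ir.samples, 125.0,
                               dc_source="zero_bin").spo2_percent)
```

The command line mirrors the library:

```bash
ppgkit fixtures --out-dir scenarios --seed 0    # materialize all scenarios
ppgkit fir-design --out coeffs.txt              # 396-tap reference band-pass
ppgkit hr --input scenarios/hr_sweep/hr_70.csv
ppgkit spo2 --red scenarios/spo2_97/red.csv --ir scenarios/spo2_97/ir.csv
```

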