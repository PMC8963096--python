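"""Synthetic multi-wavelength reflectance-PPG photocurrent generator.

A reflectance PPG photocurrent is a small pulsatile (AC) waveform, synchronous
with the heartbeat, riding on a much larger quasi-static (DC) baseline.  This
module plants known physiology — heart rate, respiratory modulation,
per-wavelength perfusion index, noise — into photocurrent traces so that every
downstream stage (analog front end, digital filters, vitals extraction) can be
tested against ground truth without recorded data.

The beat template is a sum of two Gaussian bumps standing in for the systolic
and dicrotic (diastolic) waves.  Respiration enters twice: as baseline wander
(a slow multiplicative modulation of the DC level) and as amplitude modulation
of the pulsatile component.  All randomness (beat-interval jitter, white
noise) flows from the single seed carried by :class:`PhysioGroundTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (ConfigurationError, FormatError, InvalidInputError,
                     InvalidParameterError)

__all__ = [
    "PulseShape",
    "PhysioGroundTruth",
    "OpticalChannelTrace",
    "MultiplexSchedule",
    "MultiplexedStream",
    "generate_beat_template",
    "beat_onsets",
    "synthesize_channel",
    "synthesize_pair",
    "multiplex",
    "demultiplex",
    "DEFAULT_WAVELENGTHS",
]

#: Wavelengths of the green / red / infrared LEDs, nm.
DEFAULT_WAVELENGTHS = (530, 655, 940)


@dataclass(frozen=True)
class PulseShape:
    """Two-component beat morphology: systolic bump plus dicrotic bump.

    Widths are Gaussian standard deviations in seconds.  Amplitudes are
    relative; the dicrotic amplitude must stay below the systolic one so the
    global maximum of a beat sits on the systolic wave.
    """

    systolic_center_s: float = 0.15
    systolic_width_s: float = 0.05
    systolic_amplitude: float = 1.0
    dicrotic_amplitude: float = 0.35
    dicrotic_delay_s: float = 0.40  # dicrotic center, seconds from beat onset
    dicrotic_width_s: float = 0.08

    def __post_init__(self) -> None:
        if self.systolic_width_s <= 0 or self.dicrotic_width_s <= 0:
            raise InvalidParameterError("pulse widths must be positive")
        if self.systolic_amplitude <= 0:
            raise InvalidParameterError("systolic amplitude must be positive")
        if not 0 <= self.dicrotic_amplitude < self.systolic_amplitude:
            raise InvalidParameterError(
                "dicrotic amplitude must be nonnegative and below the systolic amplitude"
            )
        if self.dicrotic_delay_s <= self.systolic_center_s:
            raise InvalidParameterError("dicrotic wave must follow the systolic wave")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Raw (un-normalized) template value at times ``t`` seconds from beat onset."""
        t = np.asarray(t, dtype=float)
        sys_bump = self.systolic_amplitude * np.exp(
            -0.5 * ((t - self.systolic_center_s) / self.systolic_width_s) ** 2
        )
        dic_bump = self.dicrotic_amplitude * np.exp(
            -0.5 * ((t - self.dicrotic_delay_s) / self.dicrotic_width_s) ** 2
        )
        return sys_bump + dic_bump


def _as_wavelength_map(value: Mapping[int, float] | float,
                       wavelengths: Sequence[int]) -> dict[int, float]:
    if isinstance(value, Mapping):
        return {int(k): float(v) for k, v in value.items()}
    return {int(w): float(value) for w in wavelengths}


@dataclass(frozen=True)
class PhysioGroundTruth:
    """Planted physiology driving the simulator.

    Perfusion index (PI) is the AC peak amplitude as a percentage of the DC
    photocurrent, per wavelength; the infrared channel typically perfuses more
    strongly than red.  DC photocurrents are in microamps and stay at or below
    1 uA, the order of magnitude a PPG photodiode delivers.
    """

    heart_rate_bpm: float = 75.0
    respiratory_rate_brpm: float = 15.0
    duration_s: float = 60.0
    perfusion_index_percent: Mapping[int, float] = field(
        default_factory=lambda: {530: 3.0, 655: 1.75, 940: 4.25}
    )
    dc_photocurrent_uA: Mapping[int, float] = field(
        default_factory=lambda: {530: 0.8, 655: 1.0, 940: 1.0}
    )
    resp_baseline_mod_percent: float = 1.0
    resp_amplitude_mod_percent: float = 10.0
    noise_white_sigma_uA: float = 0.0
    mains_amplitude_uA: float = 0.0
    mains_freq_hz: float = 50.0
    hr_jitter_percent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30.0 < self.heart_rate_bpm < 240.0:
            raise InvalidParameterError("heart rate must lie in (30, 240) bpm")
        if not 4.0 < self.respiratory_rate_brpm < 60.0:
            raise InvalidParameterError("respiratory rate must lie in (4, 60) breaths/min")
        if self.respiratory_rate_brpm >= self.heart_rate_bpm:
            raise InvalidParameterError("respiratory rate must be below the heart rate")
        if self.duration_s <= 0:
            raise InvalidParameterError("duration must be positive")
        pi = _as_wavelength_map(self.perfusion_index_percent, DEFAULT_WAVELENGTHS)
        dc = _as_wavelength_map(self.dc_photocurrent_uA, DEFAULT_WAVELENGTHS)
        for w, v in pi.items():
            # zero PI is allowed: it degenerates to a pulseless channel
            if not 0.0 <= v <= 20.0:
                raise InvalidParameterError(
                    f"perfusion index for {w} nm must lie in [0, 20] percent, got {v}"
                )
        for w, v in dc.items():
            if not 0.0 < v <= 1.0:
                raise InvalidParameterError(
                    f"DC photocurrent for {w} nm must lie in (0, 1] uA, got {v}"
                )
        object.__setattr__(self, "perfusion_index_percent", pi)
        object.__setattr__(self, "dc_photocurrent_uA", dc)
        if self.noise_white_sigma_uA < 0 or self.mains_amplitude_uA < 0:
            raise InvalidParameterError("noise amplitudes must be nonnegative")
        if not 0 <= self.hr_jitter_percent < 100:
            raise InvalidParameterError("beat jitter must lie in [0, 100) percent")


@dataclass(frozen=True)
class OpticalChannelTrace:
    """Uniformly sampled photocurrent series (microamps) for one LED wavelength."""

    wavelength_nm: int
    sample_rate_hz: float
    samples: np.ndarray
    ground_truth: PhysioGroundTruth | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample rate must be positive")
        if samples.size and samples.min() < 0:
            raise InvalidInputError("photocurrent samples must be nonnegative")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz


def generate_beat_template(shape: PulseShape, period_s: float,
                           sample_rate_hz: float) -> np.ndarray:
    """One beat of the pulse waveform, normalized to min 0 and max 1.

    Parameters
    ----------
    shape : PulseShape
        Systolic/dicrotic morphology.
    period_s : float
        Beat period; must exceed the dicrotic delay.
    sample_rate_hz : float
        Sampling rate; at least 8 samples per beat are required.
    """
    if period_s <= 0 or sample_rate_hz <= 0:
        raise InvalidParameterError("period and sample rate must be positive")
    if period_s <= shape.dicrotic_delay_s:
        raise InvalidParameterError("beat period must exceed the dicrotic delay")
    n = int(round(period_s * sample_rate_hz))
    if n < 8:
        raise InvalidParameterError("fewer than 8 samples per beat")
    t = np.arange(n) / sample_rate_hz
    raw = shape.evaluate(t)
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo)


def beat_onsets(gt: PhysioGroundTruth) -> np.ndarray:
    """Beat onset times in seconds, one per scheduled beat, first at t=0.

    Inter-beat intervals are 60/HR seconds, optionally jittered by a
    multiplicative Gaussian factor truncated at +/-3 sigma.  The schedule is
    shared by all wavelengths (one heart drives every channel).
    """
    nominal = 60.0 / gt.heart_rate_bpm
    if gt.hr_jitter_percent == 0:
        n = int(math.ceil(gt.duration_s / nominal))
        onsets = np.arange(n) * nominal
        return onsets[onsets < gt.duration_s]
    rng = np.random.default_rng([int(gt.seed), 0])
    sigma = gt.hr_jitter_percent / 100.0
    onsets = [0.0]
    while True:
        z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        nxt = onsets[-1] + nominal * (1.0 + sigma * z)
        if nxt >= gt.duration_s:
            break
        onsets.append(nxt)
    return np.asarray(onsets)


def _pulse_train(gt: PhysioGroundTruth, shape: PulseShape,
                 sample_rate_hz: float, n_samples: int) -> np.ndarray:
    """Unit pulse train: each beat is the per-beat-normalized template."""
    onsets = beat_onsets(gt)
    periods = np.diff(onsets, append=onsets[-1] + 60.0 / gt.heart_rate_bpm)
    train = np.zeros(n_samples)
    for onset, period in zip(onsets, periods):
        i0 = int(math.ceil(onset * sample_rate_hz - 1e-9))
        i1 = min(n_samples, int(math.ceil((onset + period) * sample_rate_hz - 1e-9)))
        if i1 <= i0:
            continue
        t_rel = np.arange(i0, i1) / sample_rate_hz - onset
        raw = shape.evaluate(t_rel)
        lo, hi = raw.min(), raw.max()
        if hi > lo:
            train[i0:i1] = (raw - lo) / (hi - lo)
    return train


def synthesize_channel(gt: PhysioGroundTruth, wavelength_nm: int,
                       shape: PulseShape | None = None,
                       sample_rate_hz: float = 125.0) -> OpticalChannelTrace:
    """Synthesize one wavelength's photocurrent trace.

    The signal model is::

        i(t) = DC * (1 + m_b sin(2 pi f_r t))
             + (DC * PI / 100) * pulse(t) * (1 + m_a sin(2 pi f_r t))
             + white noise + optional mains sinusoid

    where ``pulse`` is the per-beat-normalized template (min 0, max 1), so the
    clean AC peak amplitude is exactly DC*PI/100 and a valley-line AC/DC
    oracle run on the noiseless trace recovers the planted perfusion index.
    """
    wavelength_nm = int(wavelength_nm)
    if wavelength_nm not in gt.perfusion_index_percent or \
            wavelength_nm not in gt.dc_photocurrent_uA:
        raise ConfigurationError(
            f"wavelength {wavelength_nm} nm not present in the ground-truth maps"
        )
    shape = shape or PulseShape()
    n = int(round(gt.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    dc = gt.dc_photocurrent_uA[wavelength_nm]
    pi = gt.perfusion_index_percent[wavelength_nm]
    f_resp = gt.respiratory_rate_brpm / 60.0
    resp = np.sin(2 * np.pi * f_resp * t)
    baseline = dc * (1.0 + gt.resp_baseline_mod_percent / 100.0 * resp)
    ac_amp = dc * pi / 100.0
    train = _pulse_train(gt, shape, sample_rate_hz, n)
    sig = baseline + ac_amp * train * (1.0 + gt.resp_amplitude_mod_percent / 100.0 * resp)
    if gt.mains_amplitude_uA > 0:
        sig = sig + gt.mains_amplitude_uA * np.sin(2 * np.pi * gt.mains_freq_hz * t)
    if gt.noise_white_sigma_uA > 0:
        rng = np.random.default_rng([int(gt.seed), wavelength_nm])
        sig = sig + gt.noise_white_sigma_uA * rng.standard_normal(n)
    np.clip(sig, 0.0, None, out=sig)
    return OpticalChannelTrace(wavelength_nm, sample_rate_hz, sig, ground_truth=gt)


def synthesize_pair(gt: PhysioGroundTruth, shape: PulseShape | None = None,
                    sample_rate_hz: float = 125.0,
                    wavelengths: tuple[int, int] = (655, 940),
                    ) -> tuple[OpticalChannelTrace, OpticalChannelTrace]:
    """Red and infrared channels from the same heartbeat schedule."""
    return tuple(synthesize_channel(gt, w, shape, sample_rate_hz) for w in wavelengths)


@dataclass(frozen=True)
class MultiplexSchedule:
    """LED time-multiplexing plan: one LED on at a time, sampled mid-pulse.

    The LEDs alternate at ``switch_freq_hz`` (hundreds to thousands of Hz, not
    fixed by the hardware description, hence configurable); the ADC samples
    each channel in the middle of its on-pulse so no dead band is needed.
    """

    switch_freq_hz: float = 1000.0
    channel_order: tuple[int, ...] = (655, 940)
    sample_at_mid_pulse: bool = True

    def __post_init__(self) -> None:
        if self.switch_freq_hz <= 0:
            raise InvalidParameterError("switch frequency must be positive")
        if len(self.channel_order) < 1:
            raise InvalidParameterError("channel order must name at least one wavelength")
        object.__setattr__(self, "channel_order",
                           tuple(int(w) for w in self.channel_order))


@dataclass(frozen=True)
class MultiplexedStream:
    """Interleaved ADC-ready stream plus the channel index of every sample."""

    samples: np.ndarray
    channel_index: np.ndarray  # wavelength_nm per stream sample
    schedule: MultiplexSchedule
    per_channel_rate_hz: float


def multiplex(traces: Sequence[OpticalChannelTrace],
              sched: MultiplexSchedule) -> MultiplexedStream:
    """Interleave per-wavelength traces into a single mid-pulse-sampled stream.

    Each multiplexing frame emits one sample per channel in schedule order;
    the emitted value is the source channel's sample for that frame (the
    photocurrent at the midpoint of the channel's on-pulse).
    """
    if not traces:
        raise InvalidInputError("at least one trace is required")
    by_wavelength = {tr.wavelength_nm: tr for tr in traces}
    for w in sched.channel_order:
        if w not in by_wavelength:
            raise InvalidInputError(f"schedule names {w} nm but no such trace was given")
    fs = traces[0].sample_rate_hz
    n = traces[0].samples.size
    for tr in traces:
        if tr.sample_rate_hz != fs or tr.samples.size != n:
            raise InvalidInputError("all traces must share sample rate and length")
    n_ch = len(sched.channel_order)
    if sched.switch_freq_hz < 2 * fs:
        raise InvalidParameterError(
            "switch frequency must be at least twice the per-channel sample rate"
        )
    stream = np.empty(n * n_ch)
    chan = np.empty(n * n_ch, dtype=int)
    for pos, w in enumerate(sched.channel_order):
        stream[pos::n_ch] = by_wavelength[w].samples
        chan[pos::n_ch] = w
    return MultiplexedStream(stream, chan, sched, per_channel_rate_hz=fs)


def demultiplex(stream: MultiplexedStream,
                sched: MultiplexSchedule | None = None) -> list[OpticalChannelTrace]:
    """Split an interleaved stream back into per-wavelength traces.

    Channels are extracted by stride; a trailing partial frame is not padded,
    so channels early in the frame may end up one sample longer.
    """
    sched = sched or stream.schedule
    n_ch = len(sched.channel_order)
    known = set(np.unique(stream.channel_index)) if stream.channel_index.size else set()
    if not known <= set(sched.channel_order):
        raise FormatError(
            f"stream contains channel indices {sorted(known - set(sched.channel_order))} "
            "unknown to the schedule"
        )
    out = []
    for pos, w in enumerate(sched.channel_order):
        out.append(OpticalChannelTrace(w, stream.per_channel_rate_hz,
                                       stream.samples[pos::n_ch]))
    return out
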