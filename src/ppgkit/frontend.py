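"""Discrete-time model of the adjustable analog front end.

The chain mirrors a single-supply (3.3 V) op-amp board: a transimpedance
amplifier (TIA) converts photodiode current to voltage, two first-order RC
filter stages with buffers shape the band, an inverting amplifier scales the
signal, and an ADC digitizes it.  All stages operate about a virtual ground
at mid-supply (1.65 V); anything outside the rails saturates to 0 V or the
supply.  Each stage exposes its output as a "tap", like the board's test
points.

RC stages are discretized with the bilinear transform of the continuous
first-order transfer function, which maps DC and Nyquist gains exactly.  The
default sign convention is that more photocurrent raises the TIA voltage; the
inverting amplifier then flips the waveform so a blood-volume pulse appears
upright at the final tap.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InvalidParameterError
from .physio import OpticalChannelTrace

__all__ = [
    "RCStage",
    "FrontEndConfig",
    "VoltageTrace",
    "AdcTrace",
    "cutoff_from_rc",
    "tau_from_cutoff",
    "tia",
    "rc_stage_apply",
    "inverting_amp",
    "adc",
    "run_chain",
]

log = logging.getLogger(__name__)

_STAGE_KINDS = ("high-pass", "low-pass", "buffer")


def cutoff_from_rc(r_ohm: float, c_farad: float) -> float:
    """First-order corner frequency f_c = 1 / (2 pi R C), in Hz."""
    if r_ohm <= 0 or c_farad <= 0:
        raise InvalidParameterError("R and C must be positive")
    return 1.0 / (2.0 * math.pi * r_ohm * c_farad)


def tau_from_cutoff(f_c_hz: float) -> float:
    """RC time constant tau = 1 / (2 pi f_c), reported in milliseconds."""
    if f_c_hz <= 0:
        raise InvalidParameterError("cutoff frequency must be positive")
    return 1000.0 / (2.0 * math.pi * f_c_hz)


@dataclass(frozen=True)
class RCStage:
    """One first-order RC filter block followed by a buffer.

    The corner may be given directly (``cutoff_hz``, e.g. taken from the
    filter's band label) or derived from explicit component values.  A
    ``buffer`` stage (0-ohm jumpers) passes the signal through unchanged.
    """

    kind: str = "buffer"
    cutoff_hz: float | None = None
    r_ohm: float | None = None
    c_farad: float | None = None
    components_table_row: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _STAGE_KINDS:
            raise ConfigurationError(f"stage kind must be one of {_STAGE_KINDS}")
        if self.kind == "buffer":
            return
        if self.cutoff_hz is None and (self.r_ohm is None or self.c_farad is None):
            raise ConfigurationError(
                f"{self.kind} stage needs either cutoff_hz or both r_ohm and c_farad"
            )
        if self.cutoff_hz is not None and self.cutoff_hz <= 0:
            raise InvalidParameterError("cutoff frequency must be positive")
        if self.r_ohm is not None and self.r_ohm <= 0:
            raise InvalidParameterError("resistance must be positive")
        if self.c_farad is not None and self.c_farad <= 0:
            raise InvalidParameterError("capacitance must be positive")

    @property
    def corner_hz(self) -> float | None:
        """Effective corner frequency; None for a buffer."""
        if self.kind == "buffer":
            return None
        if self.cutoff_hz is not None:
            return self.cutoff_hz
        return cutoff_from_rc(self.r_ohm, self.c_farad)


@dataclass(frozen=True)
class FrontEndConfig:
    """Component values and operating point of the full conditioning chain."""

    tia_resistance_ohm: float = 22_000.0
    stage1: RCStage = field(default_factory=lambda: RCStage("high-pass", cutoff_hz=0.5))
    stage2: RCStage = field(default_factory=lambda: RCStage("low-pass", cutoff_hz=5.0))
    inv_amp_gain: float = 10.0
    supply_v: float = 3.3
    virtual_ground_v: float | None = None  # defaults to supply / 2
    adc_bits: int = 12
    adc_rate_hz: float = 100.0
    polarity: int = 1  # +1: more photocurrent raises the TIA voltage

    def __post_init__(self) -> None:
        if self.tia_resistance_ohm <= 0:
            raise InvalidParameterError("TIA resistance must be positive")
        if self.supply_v <= 0:
            raise InvalidParameterError("supply voltage must be positive")
        vg = self.supply_v / 2.0 if self.virtual_ground_v is None else self.virtual_ground_v
        if not 0 < vg < self.supply_v:
            raise InvalidParameterError("virtual ground must lie strictly inside the rails")
        object.__setattr__(self, "virtual_ground_v", vg)
        if not 8 <= int(self.adc_bits) <= 22:
            raise InvalidParameterError("ADC resolution must lie in [8, 22] bits")
        if self.adc_rate_hz <= 0:
            raise InvalidParameterError("ADC rate must be positive")
        if self.inv_amp_gain <= 0:
            raise InvalidParameterError("inverting-amplifier gain must be positive")
        if self.polarity not in (-1, 1):
            raise InvalidParameterError("polarity must be +1 or -1")


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled voltage series at one tap point of the chain."""

    samples: np.ndarray
    sample_rate_hz: float
    stage_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample rate must be positive")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz


@dataclass(frozen=True)
class AdcTrace:
    """Integer ADC codes with enough context to map back to volts."""

    codes: np.ndarray
    sample_rate_hz: float
    bits: int
    supply_v: float
    stage_label: str = "adc"

    def to_volts(self) -> VoltageTrace:
        full_scale = 2 ** self.bits - 1
        return VoltageTrace(self.codes / full_scale * self.supply_v,
                            self.sample_rate_hz, stage_label=self.stage_label)


def _clip_rails(v: np.ndarray, supply_v: float) -> np.ndarray:
    return np.clip(v, 0.0, supply_v)


def tia(photocurrent: OpticalChannelTrace, rf_ohm: float, *,
        supply_v: float = 3.3, virtual_ground_v: float | None = None,
        polarity: int = 1) -> VoltageTrace:
    """Transimpedance stage: v = VG + polarity * i * Rf, clipped to the rails.

    Photocurrent is in microamps; the feedback resistance in ohms.
    """
    if rf_ohm <= 0:
        raise InvalidParameterError("TIA feedback resistance must be positive")
    vg = supply_v / 2.0 if virtual_ground_v is None else virtual_ground_v
    v = vg + polarity * photocurrent.samples * 1e-6 * rf_ohm
    return VoltageTrace(_clip_rails(v, supply_v), photocurrent.sample_rate_hz,
                        stage_label="tia")


def rc_stage_apply(x: VoltageTrace, stage: RCStage, *,
                   supply_v: float = 3.3,
                   virtual_ground_v: float | None = None) -> VoltageTrace:
    """Apply one first-order RC stage about the virtual ground.

    The continuous transfer function (low-pass ``wc/(s+wc)`` or high-pass
    ``s/(s+wc)``) is discretized with the bilinear transform at the trace's
    sample rate.  The stage does not shift the operating point: the filter
    acts on the deviation from VG, and a high-pass stage therefore settles to
    VG for any constant input.
    """
    vg = supply_v / 2.0 if virtual_ground_v is None else virtual_ground_v
    if stage.kind == "buffer":
        return VoltageTrace(x.samples.copy(), x.sample_rate_hz, stage_label=x.stage_label)
    f_c = stage.corner_hz
    fs = x.sample_rate_hz
    if fs < 20.0 * f_c:
        msg = (f"stage corner {f_c:.3g} Hz is undersampled at {fs:.3g} Hz "
               "(fs < 20 f_c); proceeding")
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        log.warning(msg)
    wc = 2.0 * math.pi * f_c
    if stage.kind == "low-pass":
        b, a = sps.bilinear([wc], [1.0, wc], fs=fs)
    else:
        b, a = sps.bilinear([1.0, 0.0], [1.0, wc], fs=fs)
    y = vg + sps.lfilter(b, a, x.samples - vg)
    return VoltageTrace(_clip_rails(y, supply_v), fs, stage_label=stage.kind)


def inverting_amp(x: VoltageTrace, gain: float, *, supply_v: float = 3.3,
                  virtual_ground_v: float | None = None) -> VoltageTrace:
    """Inversion about the virtual ground: v_out = VG - gain (v_in - VG), clipped."""
    if gain <= 0:
        raise InvalidParameterError("gain must be positive")
    vg = supply_v / 2.0 if virtual_ground_v is None else virtual_ground_v
    v = vg - gain * (x.samples - vg)
    return VoltageTrace(_clip_rails(v, supply_v), x.sample_rate_hz, stage_label="invamp")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def adc(x: VoltageTrace, bits: int, rate_hz: float, *,
        supply_v: float = 3.3) -> AdcTrace:
    """Digitize: nearest-sample decimation to ``rate_hz``, then uniform quantization.

    The span [0, supply] maps onto 2**bits codes with round-half-away-from-zero
    on the code scale, so mid-supply on a 12-bit converter reads code 2048.
    No anti-alias filter is applied before decimation; the analog low-pass
    stage ahead of the converter plays that role, as on the board.
    """
    if rate_hz > x.sample_rate_hz:
        raise InvalidParameterError("ADC rate cannot exceed the source sample rate")
    if rate_hz <= 0:
        raise InvalidParameterError("ADC rate must be positive")
    n_out = int(math.floor(x.samples.size * rate_hz / x.sample_rate_hz))
    idx = np.clip(_round_half_away(np.arange(n_out) * x.sample_rate_hz / rate_hz
                                   ).astype(int), 0, x.samples.size - 1)
    v = x.samples[idx]
    full_scale = 2 ** int(bits) - 1
    codes = np.clip(_round_half_away(v / supply_v * full_scale), 0, full_scale)
    return AdcTrace(codes.astype(int), rate_hz, int(bits), supply_v)


def run_chain(config: FrontEndConfig,
              photocurrent: OpticalChannelTrace) -> dict[str, VoltageTrace | AdcTrace]:
    """Run the full chain and return every tap: tia, filter1, filter2, invamp, adc."""
    kw = dict(supply_v=config.supply_v, virtual_ground_v=config.virtual_ground_v)
    taps: dict[str, VoltageTrace | AdcTrace] = {}
    v = tia(photocurrent, config.tia_resistance_ohm, polarity=config.polarity, **kw)
    taps["tia"] = v
    v = rc_stage_apply(v, config.stage1, **kw)
    taps["filter1"] = VoltageTrace(v.samples, v.sample_rate_hz, stage_label="filter1")
    v = rc_stage_apply(v, config.stage2, **kw)
    taps["filter2"] = VoltageTrace(v.samples, v.sample_rate_hz, stage_label="filter2")
    v = inverting_amp(v, config.inv_amp_gain, **kw)
    taps["invamp"] = v
    taps["adc"] = adc(v, config.adc_bits, config.adc_rate_hz, supply_v=config.supply_v)
    return taps
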