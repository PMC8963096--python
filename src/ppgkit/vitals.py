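"""Physiological parameter extraction: beats, heart rate, perfusion, SpO2.

Heart rate comes from beat segmentation: systolic peaks above an adaptive
moving-average threshold, with peaks rejected when their inter-beat interval
deviates more than 30% from the running median.  Per-beat AC/DC uses the
valley-line construction: a straight line between the two valleys bracketing
a peak gives the DC value under the peak, and the AC amplitude is the peak's
height above that line.  The perfusion index is AC/DC as a percentage.

SpO2 follows the ratio-of-ratios R = (AC/DC)_red / (AC/DC)_IR, mapped to a
percentage either by the curvilinear calibration SpO2 = 104 - 17 R, by a
linear calibration K*R, or by a lookup table.  The frequency-domain method
reads the AC and DC amplitudes off an averaged short-window amplitude
spectrum instead of the time-domain valley-line construction.

The amplitude spectrum is computed from the analytic (Hilbert) signal so it
is one-sided by construction: with 310-sample windows at 125 Hz the Hamming
mainlobe is far wider than the respiratory frequency, and the negative-
frequency image of a real-FFT spectrum would otherwise pull the respiratory
argmax to the search-band edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import InvalidParameterError, UndefinedResultError

log = logging.getLogger(__name__)

__all__ = [
    "BeatSegmentation",
    "PerfusionEstimate",
    "SpO2Calibration",
    "SpO2Result",
    "SpectrumResult",
    "detect_beats",
    "compute_hr",
    "estimate_ac_dc_time",
    "ratio_of_ratios",
    "spo2_from_r",
    "compute_amplitude_spectrum",
    "find_physio_peaks",
    "spo2_frequency_domain",
    "spo2_time_domain",
]


def _samples(x) -> np.ndarray:
    return np.asarray(getattr(x, "samples", x), dtype=float)


@dataclass(frozen=True)
class BeatSegmentation:
    """Detected peaks/valleys and the accepted inter-beat intervals."""

    peak_indices: np.ndarray        # all detected systolic peak candidates
    accepted: np.ndarray            # boolean per detected peak
    valley_indices: np.ndarray      # beat-onset valleys bracketing accepted peaks
    ibis_ms: np.ndarray             # inter-beat intervals of accepted peaks
    sample_rate_hz: float

    @property
    def accepted_peaks(self) -> np.ndarray:
        return self.peak_indices[self.accepted]

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    @property
    def n_rejected(self) -> int:
        return int((~self.accepted).sum())


@dataclass(frozen=True)
class PerfusionEstimate:
    """Aggregate and per-beat AC/DC amplitudes for one channel."""

    ac: float
    dc: float
    pi_percent: float
    per_beat: list[tuple[int, float, float]]  # (beat index, ac, dc)
    method: str = "time"


@dataclass(frozen=True)
class SpO2Calibration:
    """Mapping from the ratio of ratios R to an SpO2 percentage.

    Modes: ``curvilinear`` (intercept + slope*R, default 104 - 17 R),
    ``linear`` (K*R, K from calibration), ``lut`` (monotone interpolation in
    a strictly decreasing (R, SpO2) table).
    """

    mode: str = "curvilinear"
    k: float | None = None
    intercept: float = 104.0
    slope: float = -17.0
    lut: np.ndarray | None = None  # shape (n, 2): columns R, SpO2
    clamp_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.mode not in ("curvilinear", "linear", "lut"):
            raise InvalidParameterError("calibration mode must be curvilinear|linear|lut")
        if self.mode == "linear" and self.k is None:
            raise InvalidParameterError("linear calibration requires the constant K")
        if self.mode == "lut":
            if self.lut is None:
                raise InvalidParameterError("lut calibration requires a table")
            lut = np.asarray(self.lut, dtype=float)
            if lut.ndim != 2 or lut.shape[1] != 2 or lut.shape[0] < 2:
                raise InvalidParameterError("lut must be an (n>=2, 2) array of (R, SpO2)")
            if not (np.all(np.diff(lut[:, 0]) > 0) and np.all(np.diff(lut[:, 1]) < 0)):
                raise InvalidParameterError(
                    "lut must be strictly increasing in R and decreasing in SpO2"
                )
            object.__setattr__(self, "lut", lut)

    @classmethod
    def default_lut(cls, r_grid: Sequence[float] | None = None,
                    intercept: float = 104.0, slope: float = -17.0,
                    ) -> "SpO2Calibration":
        """LUT sampled from the curvilinear map (vendor tables are proprietary)."""
        r = np.asarray(r_grid if r_grid is not None
                       else np.round(np.arange(0.2, 1.2001, 0.05), 10), dtype=float)
        return cls(mode="lut", lut=np.column_stack([r, intercept + slope * r]))


@dataclass(frozen=True)
class SpO2Result:
    r_value: float
    spo2_percent: float
    method: str
    window_s: float
    per_window: list[tuple[float, float]] = field(default_factory=list)  # (R, SpO2)


@dataclass(frozen=True)
class SpectrumResult:
    """Averaged one-sided amplitude spectrum with located physiological peaks."""

    frequencies_hz: np.ndarray
    amplitude_density: np.ndarray
    window_samples: int
    overlap_percent: float          # realized overlap
    dc_level: float                 # mean of the trace (the 0 Hz amplitude)
    respiratory_peak: tuple[float, float] | None = None  # (Hz, amplitude)
    cardiac_peak: tuple[float, float] | None = None
    respiratory_confident: bool = True


# ---------------------------------------------------------------------------
# Beat segmentation and heart rate


def detect_beats(x, fs: float | None = None, *, ma_window_s: float = 0.75,
                 alpha: float = 1.0, smooth_s: float = 0.1,
                 min_distance_s: float = 0.25,
                 ibi_tolerance: float = 0.30) -> BeatSegmentation:
    """Adaptive-threshold beat detector with interval-based peak rejection.

    Peaks are local maxima of the (lightly smoothed) signal above a moving
    threshold ``MA + alpha * rolling amplitude``, where MA is a moving average
    over ``ma_window_s`` and the rolling amplitude is the standard deviation
    of the residual over the same window.  A detected peak is rejected when
    its interval from the last accepted peak deviates more than
    ``ibi_tolerance`` (fraction) from the median candidate interval.

    Returns an empty segmentation (with a warning) when nothing is found.
    """
    fs = fs if fs is not None else getattr(x, "sample_rate_hz", None)
    if fs is None or fs < 25.0:
        raise InvalidParameterError("a sample rate of at least 25 Hz is required")
    sig = _samples(x)
    if sig.size < 3 * fs:
        raise InvalidParameterError("at least 3 seconds of signal are required")

    smooth_n = max(1, int(round(smooth_s * fs)))
    xs = uniform_filter1d(sig, smooth_n) if smooth_n > 1 else sig
    ma_n = max(3, int(round(ma_window_s * fs)))
    baseline = uniform_filter1d(xs, ma_n)
    resid = xs - baseline
    amp = np.sqrt(np.maximum(uniform_filter1d(resid ** 2, ma_n), 0.0))
    threshold = baseline + alpha * amp

    candidates, _ = sps.find_peaks(xs, distance=max(1, int(round(min_distance_s * fs))))
    candidates = candidates[xs[candidates] > threshold[candidates]]
    if candidates.size == 0:
        warnings.warn("no beats detected", RuntimeWarning, stacklevel=2)
        return BeatSegmentation(np.array([], dtype=int), np.array([], dtype=bool),
                                np.array([], dtype=int), np.array([]), fs)

    accepted = np.ones(candidates.size, dtype=bool)
    if candidates.size >= 3:
        median_ibi = float(np.median(np.diff(candidates)))
        last = candidates[0]
        for i in range(1, candidates.size):
            # reject premature peaks (spikes between beats); a long interval
            # re-synchronizes instead, and the interval itself is discarded
            # from the IBI pool below
            if candidates[i] - last < (1.0 - ibi_tolerance) * median_ibi:
                accepted[i] = False
            else:
                last = candidates[i]

    acc = candidates[accepted]
    median_acc = float(np.median(np.diff(acc))) if acc.size >= 2 else None

    valleys: list[int] = []
    if acc.size:
        pre = max(0, acc[0] - int(median_acc if median_acc else ma_n))
        if acc[0] > pre:
            valleys.append(pre + int(np.argmin(xs[pre:acc[0]])))
        for a, b in zip(acc[:-1], acc[1:]):
            valleys.append(a + int(np.argmin(xs[a:b])))
        post = min(sig.size, acc[-1] + int(median_acc if median_acc else ma_n))
        if post > acc[-1] + 1:
            valleys.append(acc[-1] + int(np.argmin(xs[acc[-1]:post])))

    ibis = np.diff(acc) / fs * 1000.0
    if ibis.size >= 3:  # guard: drop intervals that straddle a rejected beat
        med = np.median(ibis)
        ibis = ibis[np.abs(ibis - med) <= ibi_tolerance * med]
    return BeatSegmentation(candidates, accepted, np.asarray(valleys, dtype=int),
                            ibis, fs)


def compute_hr(seg: BeatSegmentation) -> float:
    """Mean heart rate in beats per minute from accepted inter-beat intervals."""
    if seg.n_accepted < 2 or seg.ibis_ms.size == 0:
        raise UndefinedResultError("at least two accepted beats are required")
    return 60_000.0 / float(np.mean(seg.ibis_ms))


# ---------------------------------------------------------------------------
# Valley-line AC/DC estimation and the ratio of ratios


def _perpendicular_dc(t_v: np.ndarray, x_v: np.ndarray, t_p: float, x_p: float,
                      t_scale: float) -> float:
    """DC at the foot of the perpendicular from the peak to the valley chord.

    Axes are rescaled (time multiplied by ``t_scale``) before the projection,
    since a perpendicular is not unit-invariant.
    """
    p1 = np.array([t_v[0] * t_scale, x_v[0]])
    p2 = np.array([t_v[1] * t_scale, x_v[1]])
    p = np.array([t_p * t_scale, x_p])
    chord = p2 - p1
    denom = float(chord @ chord)
    if denom == 0:
        return float(x_v[0])
    lam = float((p - p1) @ chord) / denom
    return float(p1[1] + lam * chord[1])


def estimate_ac_dc_time(x, seg: BeatSegmentation,
                        projection: str = "vertical") -> PerfusionEstimate:
    """Per-beat AC/DC from the valley-line construction.

    For each accepted peak bracketed by two valleys, the DC value is the
    valley line evaluated at the peak's abscissa (``vertical`` mode, unit
    invariant) or at the foot of the axis-rescaled perpendicular
    (``perpendicular`` mode); AC is the peak height above the DC value.
    Aggregate AC and DC are means over beats.
    """
    if projection not in ("vertical", "perpendicular"):
        raise InvalidParameterError("projection must be 'vertical' or 'perpendicular'")
    sig = _samples(x)
    fs = seg.sample_rate_hz
    valleys = np.asarray(seg.valley_indices)
    per_beat: list[tuple[int, float, float]] = []
    for k, p in enumerate(seg.accepted_peaks):
        right = np.searchsorted(valleys, p)
        if right == 0 or right == valleys.size:
            log.info("beat %d at sample %d not bracketed by valleys; skipped", k, p)
            continue
        v1, v2 = valleys[right - 1], valleys[right]
        t_v = np.array([v1, v2]) / fs
        x_v = sig[[v1, v2]]
        t_p, x_p = p / fs, sig[p]
        if projection == "vertical":
            dc = float(np.interp(t_p, t_v, x_v))
        else:
            x_span = float(np.ptp(sig[v1:v2 + 1])) or 1.0
            t_span = float(t_v[1] - t_v[0]) or 1.0
            dc = _perpendicular_dc(t_v, x_v, t_p, x_p, t_scale=x_span / t_span)
        per_beat.append((k, float(x_p - dc), float(dc)))
    if not per_beat:
        raise UndefinedResultError("no beat was bracketed by two valleys")
    ac = float(np.mean([b[1] for b in per_beat]))
    dc = float(np.mean([b[2] for b in per_beat]))
    if dc <= 0:
        raise UndefinedResultError("nonpositive DC estimate")
    return PerfusionEstimate(ac, dc, 100.0 * ac / dc, per_beat, method="time")


def ratio_of_ratios(red: PerfusionEstimate, ir: PerfusionEstimate) -> float:
    """R = (AC/DC)_red / (AC/DC)_IR, the predictor of SpO2."""
    if ir.dc <= 0 or red.dc <= 0:
        raise UndefinedResultError("DC estimates must be positive")
    ir_ratio = ir.ac / ir.dc
    if ir_ratio <= 0:
        raise UndefinedResultError("IR perfusion is zero; R is undefined")
    return float((red.ac / red.dc) / ir_ratio)


def spo2_from_r(r: float, cal: SpO2Calibration | None = None) -> float:
    """Map a ratio of ratios to an SpO2 percentage using the calibration."""
    cal = cal or SpO2Calibration()
    if r < 0:
        raise InvalidParameterError("R must be nonnegative")
    if cal.mode == "curvilinear":
        raw = cal.intercept + cal.slope * r
    elif cal.mode == "linear":
        raw = cal.k * r
    else:
        lut = cal.lut
        if r < lut[0, 0] or r > lut[-1, 0]:
            warnings.warn(
                f"R={r:.4g} outside the lookup table domain "
                f"[{lut[0, 0]:.3g}, {lut[-1, 0]:.3g}]; clamping to the boundary",
                RuntimeWarning, stacklevel=2)
        raw = float(np.interp(r, lut[:, 0], lut[:, 1]))
    lo, hi = cal.clamp_range
    clamped = float(np.clip(raw, lo, hi))
    if clamped != raw:
        log.info("SpO2 %.2f%% clamped to [%g, %g]", raw, lo, hi)
    return clamped


# ---------------------------------------------------------------------------
# Frequency-domain pipeline


def compute_amplitude_spectrum(x, fs: float | None = None, *,
                               window_samples: int = 310,
                               overlap_percent: float = 93.54,
                               zero_pad_to: int = 4096) -> SpectrumResult:
    """Averaged one-sided amplitude spectrum of Hamming-windowed segments.

    The global mean is removed, the analytic signal is formed (suppressing
    the negative-frequency image that would bias sub-mainlobe peaks), and the
    magnitudes of zero-padded windowed-segment FFTs are averaged and
    window-gain corrected so a sinusoid of amplitude A reads A at its bin.
    The removed mean is reported as ``dc_level`` and placed in the 0 Hz bin.
    """
    fs = fs if fs is not None else getattr(x, "sample_rate_hz", None)
    if fs is None or fs <= 0:
        raise InvalidParameterError("a positive sample rate is required")
    sig = _samples(x)
    if window_samples < 8:
        raise InvalidParameterError("window must contain at least 8 samples")
    if sig.size < window_samples:
        raise InvalidParameterError("trace is shorter than the analysis window")
    if not 0 <= overlap_percent < 100:
        raise InvalidParameterError("overlap must lie in [0, 100) percent")
    nfft = max(int(zero_pad_to), window_samples)
    hop = max(1, int(round(window_samples * (1.0 - overlap_percent / 100.0))))
    window = np.hamming(window_samples)
    gain = window.sum()

    mean = float(sig.mean())
    analytic = sps.hilbert(sig - mean)
    mags = []
    for start in range(0, sig.size - window_samples + 1, hop):
        seg = analytic[start:start + window_samples] * window
        mags.append(np.abs(np.fft.fft(seg, nfft)))
    amp = np.mean(mags, axis=0)[: nfft // 2 + 1] / gain
    amp[0] = abs(mean)
    freqs = np.arange(nfft // 2 + 1) * fs / nfft
    realized = 100.0 * (window_samples - hop) / window_samples
    return SpectrumResult(freqs, amp, window_samples, realized, mean)


def find_physio_peaks(spec: SpectrumResult,
                      resp_band: tuple[float, float] = (0.1, 0.5),
                      cardiac_band: tuple[float, float] = (0.7, 3.5),
                      ) -> SpectrumResult:
    """Locate the respiratory and cardiac peaks inside their search bands.

    The respiratory peak is flagged low-confidence when its amplitude is
    small relative to the cardiac peak (below 10%): with no respiratory
    component the band holds only window-leakage skirts of the cardiac tone,
    which sit well under that fraction, while genuine respiratory baseline
    power is comparable to or larger than the cardiac amplitude.
    """
    nyq = spec.frequencies_hz[-1]
    for name, (lo, hi) in (("respiratory", resp_band), ("cardiac", cardiac_band)):
        if not 0 <= lo < hi <= nyq:
            raise InvalidParameterError(f"{name} band must lie within [0, Nyquist]")
    if resp_band[1] > cardiac_band[0] and cardiac_band[1] > resp_band[0]:
        raise InvalidParameterError("search bands must be disjoint")

    def _peak(band):
        mask = (spec.frequencies_hz >= band[0]) & (spec.frequencies_hz <= band[1])
        if not mask.any():
            raise InvalidParameterError("band contains no spectral grid points")
        amps = spec.amplitude_density[mask]
        i = int(np.argmax(amps))
        return float(spec.frequencies_hz[mask][i]), float(amps[i])

    rf, ra = _peak(resp_band)
    cf, ca = _peak(cardiac_band)
    confident = bool(ca > 0 and ra >= 0.1 * ca)
    if not confident:
        log.info("respiratory peak at %.3f Hz is low-confidence "
                 "(amplitude %.3g vs cardiac %.3g)", rf, ra, ca)
    return replace(spec, respiratory_peak=(rf, ra), cardiac_peak=(cf, ca),
                   respiratory_confident=confident)


def spo2_frequency_domain(red, ir, fs: float | None = None, *,
                          cal: SpO2Calibration | None = None,
                          dc_source: str = "respiratory_peak",
                          resp_band: tuple[float, float] = (0.1, 0.5),
                          cardiac_band: tuple[float, float] = (0.7, 3.5),
                          window_samples: int = 310,
                          overlap_percent: float = 93.54,
                          zero_pad_to: int = 4096) -> SpO2Result:
    """SpO2 from spectral amplitudes: AC = cardiac peak, DC = respiratory peak.

    ``dc_source='zero_bin'`` uses the 0 Hz amplitude (the physical DC level)
    instead of the respiratory-peak amplitude.
    """
    if dc_source not in ("respiratory_peak", "zero_bin"):
        raise InvalidParameterError("dc_source must be 'respiratory_peak' or 'zero_bin'")
    cal = cal or SpO2Calibration()
    red_s, ir_s = (_samples(red), _samples(ir))
    if red_s.size != ir_s.size:
        raise InvalidParameterError("red and IR traces must be simultaneous and equal length")
    ratios = {}
    for name, tr in (("red", red), ("ir", ir)):
        spec = compute_amplitude_spectrum(tr, fs, window_samples=window_samples,
                                          overlap_percent=overlap_percent,
                                          zero_pad_to=zero_pad_to)
        spec = find_physio_peaks(spec, resp_band, cardiac_band)
        ac = spec.cardiac_peak[1]
        if dc_source == "respiratory_peak":
            if not spec.respiratory_confident:
                raise UndefinedResultError(
                    f"no distinct respiratory peak in the {name} channel; "
                    "cannot use it as the DC amplitude"
                )
            dc = spec.respiratory_peak[1]
        else:
            dc = spec.dc_level
        if dc <= 0:
            raise UndefinedResultError(f"nonpositive spectral DC in the {name} channel")
        ratios[name] = ac / dc
    if ratios["ir"] <= 0:
        raise UndefinedResultError("IR spectral perfusion is zero; R is undefined")
    r = ratios["red"] / ratios["ir"]
    window_s = window_samples / (fs or getattr(red, "sample_rate_hz"))
    return SpO2Result(float(r), spo2_from_r(r, cal),
                      method="frequency-curvilinear", window_s=window_s)


def spo2_time_domain(red, ir, fs: float | None = None, *,
                     cal: SpO2Calibration | None = None,
                     method: str = "curvilinear",
                     window_s: float = 40.0,
                     projection: str = "vertical",
                     smooth_s: float = 0.1,
                     detector_kwargs: dict | None = None) -> SpO2Result:
    """Time-domain SpO2: segmentation, valley-line AC/DC, ratio of ratios, calibration.

    The traces are split into non-overlapping windows (default 40 s; a
    shorter trace is analyzed whole), each window yields one R from
    window-averaged AC/DC, and the per-window SpO2 values are averaged.
    Both channels are pre-smoothed by the same short moving average
    (``smooth_s``) before segmentation and amplitude estimation; identical
    linear filtering scales both channels' AC equally, so R is unaffected
    while peak/valley noise bias is suppressed.
    """
    if method not in ("curvilinear", "lut", "linear"):
        raise InvalidParameterError("method must be curvilinear|lut|linear")
    if cal is None:
        cal = SpO2Calibration.default_lut() if method == "lut" else SpO2Calibration()
    fs = fs if fs is not None else getattr(red, "sample_rate_hz", None)
    if fs is None:
        raise InvalidParameterError("a sample rate is required")
    red_s, ir_s = _samples(red), _samples(ir)
    if red_s.size != ir_s.size:
        raise InvalidParameterError("red and IR traces must be simultaneous and equal length")
    kw = dict(detector_kwargs or {})
    kw.setdefault("smooth_s", 0.0)  # channels are pre-smoothed below
    smooth_n = max(1, int(round(smooth_s * fs)))
    if smooth_n > 1:
        red_s = uniform_filter1d(red_s, smooth_n)
        ir_s = uniform_filter1d(ir_s, smooth_n)
    win_n = int(round(window_s * fs))
    if red_s.size < win_n:
        win_n = red_s.size
    per_window: list[tuple[float, float]] = []
    for start in range(0, red_s.size - win_n + 1, win_n):
        sl = slice(start, start + win_n)
        estimates = {}
        for name, chan in (("red", red_s[sl]), ("ir", ir_s[sl])):
            seg = detect_beats(chan, fs, **kw)
            estimates[name] = estimate_ac_dc_time(chan, seg, projection=projection)
        r = ratio_of_ratios(estimates["red"], estimates["ir"])
        per_window.append((r, spo2_from_r(r, cal)))
    if not per_window:
        raise UndefinedResultError("trace too short for a single analysis window")
    r_mean = float(np.mean([w[0] for w in per_window]))
    spo2_mean = float(np.mean([w[1] for w in per_window]))
    return SpO2Result(r_mean, spo2_mean, method=f"time-{method}",
                      window_s=win_n / fs, per_window=per_window)
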