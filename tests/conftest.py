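import numpy as np
import pytest

import ppgkit as pk


@pytest.fixture(scope="session")
def paper_bandpass():
    """The reference 396-tap 0.5-5 Hz band-pass design (designed once)."""
    return pk.design_equiripple(pk.FIRSpec())


@pytest.fixture(scope="session")
def clean_gt():
    """Noiseless, modulation-free physiology: the simplest recoverable signal."""
    return pk.PhysioGroundTruth(
        heart_rate_bpm=72.0,
        respiratory_rate_brpm=15.0,
        duration_s=60.0,
        perfusion_index_percent={655: 1.75, 940: 4.25},
        dc_photocurrent_uA={655: 1.0, 940: 1.0},
        resp_baseline_mod_percent=0.0,
        resp_amplitude_mod_percent=0.0,
        noise_white_sigma_uA=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_ir_trace(clean_gt):
    return pk.synthesize_channel(clean_gt, 940, sample_rate_hz=125.0)


def sine_probe_gain(stage, freq_hz, fs, vg=1.65, amplitude=0.1, cycles=12):
    """Measured magnitude gain of an RC stage at one frequency.

    The steady-state output amplitude is extracted by quadrature projection
    after discarding the first half of the record (transient).
    """
    duration = max(cycles / freq_hz, 5.0)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = pk.VoltageTrace(vg + amplitude * np.sin(2 * np.pi * freq_hz * t), fs)
    y = pk.rc_stage_apply(x, stage, virtual_ground_v=vg)
    tail = slice(n // 2, None)
    resid = y.samples[tail] - vg
    ref = np.exp(-2j * np.pi * freq_hz * t[tail])
    est_amp = 2.0 * np.abs(np.mean(resid * ref))
    return est_amp / amplitude
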