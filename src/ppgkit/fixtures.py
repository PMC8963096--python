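"""Named synthetic scenarios materialized on disk.

Each scenario writes traces plus ground-truth sidecars under its own
directory, and a JSON manifest records files and seeds so a run can be
reproduced exactly.  The scenarios cover the package's headline analyses:

- ``filter1_paper`` / ``filter2_paper``: front-end chains with 0.5-5 Hz and
  0.5-10 Hz analog band-pass configurations applied to a synthetic IR trace.
- ``hr_sweep``: noiseless 60 s traces at 50-120 bpm for heart-rate recovery.
- ``spo2_97``: a red/IR pair with planted ratio-of-ratios 7/17, i.e. an SpO2
  of 97% under the curvilinear calibration 104 - 17 R.
- ``spectral_peaks``: respiration at 11.7 breaths/min (0.195 Hz) and heart
  rate 86.4 bpm (1.44 Hz) for spectral peak localization.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import io as pio
from .frontend import FrontEndConfig, RCStage, run_chain
from .physio import PhysioGroundTruth, synthesize_channel, synthesize_pair

__all__ = ["generate_fixtures", "spo2_97_ground_truth", "SPO2_97_R"]

#: Planted ratio of ratios in the ``spo2_97`` scenario: PI_red/PI_IR = 1.75/4.25.
SPO2_97_R = 7.0 / 17.0


def spo2_97_ground_truth(seed: int = 0, duration_s: float = 40.0,
                         noise_sigma_uA: float = 0.001) -> PhysioGroundTruth:
    """Physiology whose red/IR perfusion ratio maps to SpO2 = 97%.

    Perfusion indices 1.75% (red) and 4.25% (IR) on equal DC levels give
    R = 7/17 and 104 - 17 R = 97.  The default noise sigma is 0.1% of the DC
    level (mild photodetector noise).
    """
    return PhysioGroundTruth(
        heart_rate_bpm=75.0,
        respiratory_rate_brpm=15.0,
        duration_s=duration_s,
        perfusion_index_percent={655: 1.75, 940: 4.25},
        dc_photocurrent_uA={655: 1.0, 940: 1.0},
        noise_white_sigma_uA=noise_sigma_uA,
        seed=seed,
    )


def spectral_peaks_ground_truth(seed: int = 0,
                                duration_s: float = 120.0) -> PhysioGroundTruth:
    """Noiseless physiology with cardiac 1.44 Hz and respiratory 0.195 Hz."""
    return PhysioGroundTruth(
        heart_rate_bpm=86.4,
        respiratory_rate_brpm=11.7,
        duration_s=duration_s,
        perfusion_index_percent={655: 1.75, 940: 4.25},
        dc_photocurrent_uA={655: 1.0, 940: 1.0},
        resp_baseline_mod_percent=2.0,
        noise_white_sigma_uA=0.0,
        seed=seed,
    )


def _filter_scenario(out: Path, name: str, lp_cutoff_hz: float,
                     seed: int) -> dict:
    gt = PhysioGroundTruth(duration_s=12.0, seed=seed)
    trace = synthesize_channel(gt, 940, sample_rate_hz=1000.0)
    config = FrontEndConfig(
        tia_resistance_ohm=22_000.0,
        stage1=RCStage("high-pass", cutoff_hz=0.5, r_ohm=1e6, c_farad=1e-6),
        stage2=RCStage("low-pass", cutoff_hz=lp_cutoff_hz,
                       r_ohm=680e3 if lp_cutoff_hz == 5.0 else 330e3,
                       c_farad=47e-9),
        inv_amp_gain=10.0,
        adc_rate_hz=100.0,
    )
    taps = run_chain(config, trace)
    d = out / name
    d.mkdir(parents=True, exist_ok=True)
    files = {}
    pio.write_trace(trace, d / "photocurrent.csv")
    files["photocurrent"] = f"{name}/photocurrent.csv"
    for label in ("tia", "filter1", "filter2", "invamp", "adc"):
        fname = f"{label}.csv"
        pio.write_trace(taps[label], d / fname)
        files[label] = f"{name}/{fname}"
    pio.write_ground_truth(gt, d / "ground_truth.yaml")
    files["ground_truth"] = f"{name}/ground_truth.yaml"
    cfg = pio.RunConfig(physio=gt, frontend=config, seed=seed)
    pio.save_config(cfg, d / "config.yaml")
    files["config"] = f"{name}/config.yaml"
    return {"files": files, "seed": seed, "lp_cutoff_hz": lp_cutoff_hz}


def generate_fixtures(out_dir, seed: int = 0) -> dict:
    """Write every named scenario under ``out_dir`` and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed)
    manifest: dict = {"seed": seed, "scenarios": {}}

    manifest["scenarios"]["filter1_paper"] = _filter_scenario(
        out, "filter1_paper", 5.0, seed)
    manifest["scenarios"]["filter2_paper"] = _filter_scenario(
        out, "filter2_paper", 10.0, seed + 1)

    # hr_sweep: noiseless traces across the physiological range
    d = out / "hr_sweep"
    d.mkdir(exist_ok=True)
    sweep_files = {}
    for i, hr in enumerate(range(50, 121, 10)):
        gt = PhysioGroundTruth(heart_rate_bpm=float(hr), duration_s=60.0,
                               noise_white_sigma_uA=0.0, seed=seed + 10 + i)
        tr = synthesize_channel(gt, 940, sample_rate_hz=125.0)
        pio.write_trace(tr, d / f"hr_{hr}.csv")
        pio.write_ground_truth(gt, d / f"hr_{hr}_ground_truth.yaml")
        sweep_files[str(hr)] = {"trace": f"hr_sweep/hr_{hr}.csv",
                                "ground_truth": f"hr_sweep/hr_{hr}_ground_truth.yaml",
                                "seed": seed + 10 + i}
    manifest["scenarios"]["hr_sweep"] = {"files": sweep_files,
                                         "hr_bpm": list(range(50, 121, 10))}

    # spo2_97: planted ratio of ratios 7/17
    d = out / "spo2_97"
    d.mkdir(exist_ok=True)
    gt = spo2_97_ground_truth(seed=seed + 100)
    red, ir = synthesize_pair(gt, sample_rate_hz=125.0)
    pio.write_trace(red, d / "red.csv")
    pio.write_trace(ir, d / "ir.csv")
    pio.write_ground_truth(gt, d / "ground_truth.yaml")
    manifest["scenarios"]["spo2_97"] = {
        "files": {"red": "spo2_97/red.csv", "ir": "spo2_97/ir.csv",
                  "ground_truth": "spo2_97/ground_truth.yaml"},
        "seed": seed + 100,
        "planted_r": SPO2_97_R,
        "expected_spo2_percent": 104.0 - 17.0 * SPO2_97_R,
    }

    # spectral_peaks: 0.195 Hz respiration, 1.44 Hz cardiac
    d = out / "spectral_peaks"
    d.mkdir(exist_ok=True)
    gt = spectral_peaks_ground_truth(seed=seed + 200)
    red, ir = synthesize_pair(gt, sample_rate_hz=125.0)
    pio.write_trace(red, d / "red.csv")
    pio.write_trace(ir, d / "ir.csv")
    pio.write_ground_truth(gt, d / "ground_truth.yaml")
    manifest["scenarios"]["spectral_peaks"] = {
        "files": {"red": "spectral_peaks/red.csv", "ir": "spectral_peaks/ir.csv",
                  "ground_truth": "spectral_peaks/ground_truth.yaml"},
        "seed": seed + 200,
        "respiratory_hz": 11.7 / 60.0,
        "cardiac_hz": 86.4 / 60.0,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
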