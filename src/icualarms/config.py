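"""Pipeline configuration with every tunable constant in one place.

Each section mirrors one pipeline stage.  Constants that come from the
published decision rules (flat-line duration, arrhythmia definitions, the
46 bpm bradycardia threshold, the 5x false-negative score weight) are noted
as such; the remaining values are this package's own defaults and can be
overridden from a YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    # flat line: exactly constant value sustained >= 2 s (published rule)
    flat_min_duration_s: float = 2.0
    flat_tolerance: float = 0.0        # raw-unit tolerance; 0 = true constancy
    baseline_poly_order: int = 5       # published choice for ECG detrending
    # arterial-pressure abnormality thresholds (cited beat-quality criteria)
    bp_systolic_max: float = 300.0     # mmHg
    bp_diastolic_min: float = 20.0     # mmHg
    bp_map_min: float = 30.0           # mmHg
    bp_map_max: float = 200.0          # mmHg
    bp_pulse_pressure_min: float = 20.0  # mmHg
    bp_neg_slope_max: float = -400.0   # mmHg/s (-40 mmHg/100 ms; steeper = abnormal)
    bp_delta_systolic_max: float = 20.0  # mmHg beat-to-beat
    bp_delta_diastolic_max: float = 20.0  # mmHg beat-to-beat
    # the heart-rate-range and period-change criteria exist but are disabled
    bp_use_hr_criterion: bool = False
    bp_hr_min_bpm: float = 20.0
    bp_hr_max_bpm: float = 200.0
    bp_use_period_change_criterion: bool = False
    bp_period_change_max_s: float = 2.0 / 3.0


@dataclass
class DetectConfig:
    ssf_window_s: float = 0.128        # slope-sum-function window, both passes
    refractory_s: float = 0.2          # 300 bpm physiological ceiling
    min_fs: float = 100.0              # wavelet detector needs >=100 Hz
    # amplitude-envelope bands (Hz)
    band_low: tuple[float, float] = (0.5, 6.0)
    band_qrs: tuple[float, float] = (5.0, 25.0)
    band_high: tuple[float, float] = (30.0, 90.0)
    envelope_smooth_s: float = 0.1
    kappa_pacing: float = 0.7          # high-band / QRS-band ratio for spikes
    kappa_twave: float = 0.3           # QRS-band fraction of median for T waves
    vt_low_ratio_min: float = 0.2      # low/QRS envelope ratio for wide beats
    vt_high_ratio_max: float = 0.6     # high/QRS envelope ratio bound


@dataclass
class FeatureConfig:
    # analysis windows in seconds from record start (alarm at 300 s)
    window_asystole: tuple[float, float] = (284.0, 300.0)
    window_bradycardia: tuple[float, float] = (280.0, 300.0)
    window_tachycardia: tuple[float, float] = (280.0, 300.0)
    window_vfib: tuple[float, float] = (284.0, 300.0)
    window_vtach: tuple[float, float] = (290.0, 300.0)
    # true-VF training augmentation: extra window starts, each ending at 300 s
    vf_augment_starts: tuple[float, ...] = (293.0, 294.0, 295.0, 296.0)
    swing_sub_window_s: float = 1.0
    spectral_band: tuple[float, float] = (0.5, 15.0)
    sqi_beat_half_window_s: float = 0.25
    sharpness_half_window_s: float = 0.06
    periodicity_lag_range_s: tuple[float, float] = (0.24, 2.4)


@dataclass
class ModelConfig:
    n_trees: int = 301                 # published forest size
    n_trees_selection: int = 21        # smaller forests inside LOOCV curves
    cost_fp: float = 1.0
    cost_fn_grid: tuple[float, ...] = tuple(round(1.0 + 0.1 * i, 1) for i in range(11))
    selection_repeats: int = 5         # published: whole procedure run 5 times
    plateau_tol: float = 0.5           # score units on the median curve
    expansion: float = 1.2             # final count = ceil(1.2 * plateau point)


@dataclass
class BradyConfig:
    threshold_bpm: float = 46.0        # published rule: slower than 46 bpm = true
    run_beats: int = 4


@dataclass
class SynthConfig:
    fs: float = 250.0
    duration_s: float = 300.0
    alarm_time_s: float = 300.0


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    brady: BradyConfig = field(default_factory=BradyConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)


def _apply(section, overrides: dict):
    for key, value in overrides.items():
        if not hasattr(section, key):
            raise KeyError(f"unknown config key {key!r} in section "
                           f"{type(section).__name__}")
        current = getattr(section, key)
        if isinstance(current, tuple):
            value = tuple(value)
        setattr(section, key, value)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a PipelineConfig, optionally overlaying a YAML file.

    The YAML file holds one mapping per section, e.g.::

        brady:
          threshold_bpm: 46
        model:
          n_trees: 301
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for section_name, overrides in data.items():
        if not hasattr(cfg, section_name):
            raise KeyError(f"unknown config section {section_name!r}")
        _apply(getattr(cfg, section_name), overrides or {})
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)
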