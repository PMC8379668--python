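"""Pipeline configuration: a validated YAML profile.

The default profile ships the study device settings (250 Hz sampling,
145 Hz stimulation, 1-min-on/5-min-off duty cycle, the six canonical bands,
14 five-second test windows, 4 connectivity comparisons). Unknown keys are
rejected by name so typos fail loudly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .io import BandDef

__all__ = ["PipelineConfig", "DEFAULT_PROFILE"]

DEFAULT_PROFILE: dict = {
    "paths": {
        "catalog": "catalog.csv",
        "recordings_dir": ".",
        "events": "events.csv",
        "output_dir": "out",
    },
    "preprocessing": {
        "notch_center_hz": 105.0,
        "notch_bandwidth_hz": 4.0,
        "min_flat_ms": 20.0,
        "max_flat_ms": 200.0,
        "guard_ms": 8.0,
    },
    "segmentation": {
        "stim_freq_hz": 145.0,
        "bandwidth_hz": 4.0,
        "threshold_z": 0.0,
        "min_duration_s": 10.0,
        "merge_gap_s": 2.0,
        "control_guard_s": 10.0,
    },
    "bands": [
        {"name": "delta", "low_hz": 1.0, "high_hz": 5.0},
        {"name": "theta", "low_hz": 5.0, "high_hz": 10.0},
        {"name": "alpha", "low_hz": 10.0, "high_hz": 15.0},
        {"name": "beta", "low_hz": 15.0, "high_hz": 25.0},
        {"name": "low_gamma", "low_hz": 30.0, "high_hz": 40.0},
        {"name": "high_gamma", "low_hz": 70.0, "high_hz": 90.0},
    ],
    "analysis": {
        "window_s": [-20.0, 70.0],
        "baseline_ref_s": [-20.0, -10.0],
        "test_baseline_s": [-10.0, 0.0],
        "window_length_s": 5.0,
        "n_windows": 14,
        "n_comparisons": 4,
        "alpha": 0.05,
        "response_channel": "HPC1-HPC2",
        "response_bands": ["delta", "theta", "beta", "high_gamma"],
        "connectivity_bands": ["theta", "beta", "high_gamma"],
    },
    "simulate": {
        "n_recordings": 12,
        "duration_s": 180.0,
        "sampling_rate_hz": 250.0,
        "duty_on_s": 60.0,
        "duty_off_s": 300.0,
        "artifact_amplitude": 0.5,
        "file_format": "edf",
    },
    "seed": 0,
}


def _merge_strict(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {here!r} must be a mapping")
            out[key] = _merge_strict(base[key], val, here)
        else:
            out[key] = val
    return out


@dataclass
class PipelineConfig:
    profile: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_PROFILE))

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PipelineConfig":
        """Default profile, optionally overridden by a YAML file.

        Every key in the file must exist in the default profile; unknown
        keys raise ConfigError naming the offending key.
        """
        if path is None:
            return cls()
        text = Path(path).read_text()
        override = yaml.safe_load(text) or {}
        if not isinstance(override, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls(profile=_merge_strict(DEFAULT_PROFILE, override))

    def __getitem__(self, key: str):
        return self.profile[key]

    @property
    def bands(self) -> list[BandDef]:
        return [
            BandDef(b["name"], float(b["low_hz"]), float(b["high_hz"]))
            for b in self.profile["bands"]
        ]

    def band(self, name: str) -> BandDef:
        for b in self.bands:
            if b.name == name:
                return b
        raise ConfigError(f"band {name!r} not in config band table")

    def dump(self) -> str:
        return yaml.safe_dump(self.profile, sort_keys=False)
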