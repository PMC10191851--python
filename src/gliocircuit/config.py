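"""Pipeline configuration: defaults, validation, YAML round-trip.

Every numeric default used by the analysis stages is named here and can
be overridden from a YAML/JSON file; unknown keys are rejected so typos
cannot silently fall back to defaults.  The effective configuration is
echoed into the run report for provenance.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "PipelineConfig", "load_config"]

STAGES = ("simulate", "ecog", "decode", "connect", "spectra", "mea", "stats")

DEFAULTS: dict = {
    "stages": list(STAGES),
    "seed": 0,
    "out_dir": "gliocircuit_out",
    "log_level": "INFO",
    "simulate": {
        "ecog": {
            "n_participants": 4,
            "n_channels": 12,
            "fraction_tumour_channels": 0.5,
            "fs": 1200.0,
            "n_trials_per_condition": 8,
            "tumour_amplitude_ratio": 2.0,
            "condition_effect_size": 1.0,
            "noise_sd": 1.0,
        },
        "voxel": {
            "n_voxels_per_hemisphere": 60,
            "fs": 200.0,
            "duration": 60.0,
            "alpha_freq": 10.0,
            "base_coupling": 0.3,
            "n_lesion_voxels": 10,
            "lesion_coupling_boost": 3.0,
            "noise_sd": 1.0,
        },
        "raster": {
            "n_wells": 1,
            "n_electrodes_per_well": 16,
            "duration": 300.0,
            "background_rate": 0.5,
            "n_network_bursts": 5,
            "burst_electrode_fraction": 0.5,
            "spikes_per_burst": 80,
            "within_burst_jitter_sd_ms": 1.0,
        },
        "spectrum": {
            "offset_b": 1.0,
            "knee_k": 0.0,
            "exponent_chi": 2.0,
            "peak_centre_hz": 40.0,
            "peak_height": 0.5,
            "peak_width_hz": 4.0,
            "noise_sd_log": 0.02,
        },
        "cohort": {
            "n_per_group": 100,
            "median_low_weeks": 71.0,
            "median_high_weeks": 123.0,
            "censoring_fraction": 0.2,
        },
    },
    "ecog": {
        "kurtosis_max": 5.0,
        "max_latency_s": 2.0,
        "hgp_band": [70.0, 110.0],
        "fir_order": 300,
        "task_window_s": [0.0, 1.0],
        "tumour_radius_mm": 10.0,
    },
    "decoding": {"window_s": [-0.5, 0.5], "cost": 1.0, "n_time_bins": 10},
    "megconn": {
        "band": [8.0, 12.0],
        "segment_s": 1.0,
        "overlap": 0.5,
        "test_method": "mirror_block",
        "n_blocks": 12,
        "fdr_alpha": 0.05,
    },
    "spectral": {"n_tapers": 29, "band": [1.0, 50.0], "gamma_band": [30.0, 50.0]},
    "mea": {
        "min_spikes_per_burst": 5,
        "max_isi_s": 0.1,
        "min_network_spikes": 50,
        "min_electrode_frac": 0.35,
        "active_rate_per_min": 5.0,
        "auncc_bin_s": 0.005,
        "auncc_max_lag_s": 0.1,
        "wmfr_mode": "mean_active",
    },
    "stats": {"fdr_alpha": 0.05},
}


class ConfigError(ValueError):
    pass


def _validate(user: dict, schema: dict, path: str = "") -> None:
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(schema[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {here} must be a mapping")
            _validate(val, schema[key], here)


def _merge(base: dict, user: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in user.items():
        if isinstance(val, dict):
            out[key] = _merge(base[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


class PipelineConfig:
    """Validated, default-filled pipeline configuration."""

    def __init__(self, user: dict | None = None):
        user = user or {}
        _validate(user, DEFAULTS)
        self._cfg = _merge(DEFAULTS, user)
        bad = set(self._cfg["stages"]) - set(STAGES)
        if bad:
            raise ConfigError(
                f"unknown stages {sorted(bad)}; valid stages: {list(STAGES)}"
            )

    def __getitem__(self, key):
        return self._cfg[key]

    @property
    def stages(self) -> list[str]:
        return [s for s in STAGES if s in self._cfg["stages"]]

    @property
    def seed(self) -> int:
        return int(self._cfg["seed"])

    def as_dict(self) -> dict:
        return copy.deepcopy(self._cfg)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self._cfg, f, sort_keys=True)

    def to_json(self) -> str:
        return json.dumps(self._cfg, sort_keys=True, indent=2)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML/JSON config file, apply overrides, fill defaults."""
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
    if overrides:
        _validate(overrides, DEFAULTS)
        user = _merge_user(user, overrides)
    return PipelineConfig(user)


def _merge_user(a: dict, b: dict) -> dict:
    out = copy.deepcopy(a)
    for k, v in b.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_user(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out
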