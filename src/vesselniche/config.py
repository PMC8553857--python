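"""YAML pipeline configuration: schema, defaults and validation.

One config file drives the whole pipeline.  Defaults are the published
analysis parameters (10 μm background radius, 10^4 μm^3 volume filter, 10 μm
seeding diameter, 2x down-sampling, 5 μm proximity cutoff, marker spot
sizes); parameters that were never printed (channel thresholds, the
co-localization fraction) default to documented conventions ("otsu", 0.05).
All lengths are micrometres — keys carry a ``_um`` suffix and unknown keys
are hard errors with a nearest-match suggestion, so a stray ``bg_radius_px``
cannot silently change units.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "ValidationReport", "load_config", "validate_config", "default_config"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            raise ConfigError("; ".join(self.errors))


def default_config() -> dict:
    return {
        "output_dir": "vesselniche_out",
        "seed": 0,
        "spacing_um": [1.3, 1.3, 2.5],
        "inputs": None,
        "synthetic": None,
        "segmentation": {
            "bg_radius_um": 10.0,
            "min_vessel_volume_um3": 1.0e4,
            "split_seed_diameter_um": 10.0,
            "downsample_factor": 2,
            "channel_thresholds": {"CD31": "otsu", "Emcn": "otsu"},
            "spot_threshold": None,
        },
        "phenotype": {"colocalization_fraction": 0.05},
        "stats": {
            "proximity_cutoff_um": 5.0,
            "histogram_edges_um": [0, 5, 10, 20, 50, 100],
            "use_ground_truth_cells": False,
        },
        "voi": None,
    }


# allowed keys per section (None = leaf)
_SCHEMA: dict = {
    "output_dir": None,
    "seed": None,
    "spacing_um": None,
    "inputs": {"cd31": None, "emcn": None, "cells": None, "marker": None},
    "synthetic": {
        "extent_um": None,
        "n_vessels_per_layer": None,
        "layer_spec": None,
        "n_cells": None,
        "marker": None,
        "affinity": {
            "target_phenotype": None,
            "law": None,
            "scale_um": None,
            "max_um": None,
            "fraction_background": None,
        },
        "noise": {
            "psf_sigma_um": None,
            "background_level": None,
            "poisson_gain": None,
            "gaussian_sigma": None,
            "rng_seed": None,
        },
    },
    "segmentation": {
        "bg_radius_um": None,
        "min_vessel_volume_um3": None,
        "split_seed_diameter_um": None,
        "downsample_factor": None,
        "channel_thresholds": None,
        "spot_threshold": None,
    },
    "phenotype": {"colocalization_fraction": None},
    "stats": {"proximity_cutoff_um": None, "histogram_edges_um": None, "use_ground_truth_cells": None},
    "voi": {
        "shape": None,
        "origin_um": None,
        "extent_um": None,
        "center_um": None,
        "diameter_um": None,
        "axis": None,
        "id": None,
        "preset": None,
    },
}

_POSITIVE_FIELDS = [
    ("segmentation", "bg_radius_um"),
    ("segmentation", "min_vessel_volume_um3"),
    ("segmentation", "split_seed_diameter_um"),
    ("stats", "proximity_cutoff_um"),
]


def _check_keys(given: dict, allowed: dict, prefix: str, report: ValidationReport) -> None:
    for key, value in given.items():
        if key not in allowed:
            suggestion = difflib.get_close_matches(key, allowed.keys(), n=1, cutoff=0.5)
            msg = f"unknown config key {prefix}{key!r}"
            if suggestion:
                msg += f" (did you mean {suggestion[0]!r}?)"
            report.errors.append(msg)
        elif isinstance(allowed[key], dict) and isinstance(value, dict):
            _check_keys(value, allowed[key], f"{prefix}{key}.", report)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config) -> ValidationReport:
    """Validate a config mapping or YAML path; never raises by itself."""
    report = ValidationReport()
    if not isinstance(config, dict):
        path = Path(config)
        if not path.exists():
            report.errors.append(f"config file {path} does not exist")
            return report
        config = yaml.safe_load(path.read_text()) or {}
    _check_keys(config, _SCHEMA, "", report)
    merged = _merge(default_config(), config)

    for section, key in _POSITIVE_FIELDS:
        val = merged.get(section, {}).get(key)
        if val is None or not isinstance(val, (int, float)) or val <= 0:
            report.errors.append(f"{section}.{key} must be a positive number, got {val!r}")
    df = merged["segmentation"].get("downsample_factor")
    if not isinstance(df, int) or df < 1:
        report.errors.append(f"segmentation.downsample_factor must be a positive integer, got {df!r}")
    cf = merged["phenotype"].get("colocalization_fraction")
    if not isinstance(cf, (int, float)) or not 0 <= cf < 1:
        report.errors.append(f"phenotype.colocalization_fraction must lie in [0, 1), got {cf!r}")
    sp = merged.get("spacing_um")
    if not (isinstance(sp, (list, tuple)) and len(sp) == 3 and all(isinstance(s, (int, float)) and s > 0 for s in sp)):
        report.errors.append(f"spacing_um must be three positive numbers (x, y, z), got {sp!r}")

    # the warning reflects what the *user* wrote: an explicit threshold table
    # that omits a channel falls back to Otsu for it
    user_thr = (config.get("segmentation") or {}).get("channel_thresholds")
    if isinstance(user_thr, dict):
        for ch in ("CD31", "Emcn"):
            if ch not in user_thr:
                report.warnings.append(f"no threshold configured for channel {ch}; falling back to 'otsu'")

    if merged.get("inputs") is None and merged.get("synthetic") is None:
        report.errors.append("config must provide either 'inputs' (image paths) or 'synthetic' (phantom parameters)")

    voi = merged.get("voi")
    if isinstance(voi, dict):
        ext = voi.get("extent_um")
        if voi.get("shape", "box") == "box" and not voi.get("preset") and (
            ext is None or any(not isinstance(e, (int, float)) or e <= 0 for e in ext)
        ):
            report.errors.append(f"voi.extent_um must be three positive numbers, got {ext!r}")
    return report


def load_config(config_path) -> dict:
    """Load, validate and fill a YAML config with the published defaults."""
    report = validate_config(config_path)
    report.raise_if_failed()
    raw = yaml.safe_load(Path(config_path).read_text()) or {}
    merged = _merge(default_config(), raw)
    thr = merged["segmentation"].setdefault("channel_thresholds", {})
    for ch in ("CD31", "Emcn"):
        thr.setdefault(ch, "otsu")
    return merged
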