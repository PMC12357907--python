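"""Run configuration: defaults, YAML loading and validation.

Default values encode the published analysis choices where stated (solidity
< 0.7, overlap < 60%, huang2 on DAPI/MBP, huang on O4, DAPI binary ops
erode/open/dilate/watershed, O4 erode/open, alpha = 0.05); everything else is
"unstated, chosen" and config-exposed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": None,
    "mode": "simulate",  # simulate | manifest
    "simulation": {
        "n_lines_per_group": 4,
        "n_fov_per_line": 6,
        "marker": "MBP",
        "image_shape": [192, 192],
        "n_nuclei": 6,
        "n_cells": 4,
        "segment_len_range": [12.0, 20.0],  # base tree-segment length (px)
        "bleed_coefficient": 0.0,
        "illumination_amplitude": 0.15,
        "photon_scale": 8.0,
        "read_sd": 1.5,
        "branch_length_effect": 0.0,  # multiplicative shift for the SCZ group
        "line_scale_sd": 0.02,  # between-line log-scale SD of branch length
    },
    "manifest": None,  # CSV with columns path,group,line,fov  (mode=manifest)
    "preprocess": {
        "pseudo_flat_field": {"blur_radius_px": None},
        "median_smooth": {"radius_px": 2},
        "subtract_background_paraboloid": {"radius_px": 50},
        "enhance_contrast": {"saturated_fraction": 0.0035},
    },
    "segment": {
        "threshold_variant": {"DAPI": "huang2", "MBP": "huang2", "O4": "huang"},
        "binary_ops": {"DAPI": ["erode", "open", "dilate", "watershed"],
                       "O4": ["erode", "open"], "MBP": []},
        "min_area_px": 20,
        "solidity_cutoff": 0.7,
        "overlap_cutoff": 0.6,
    },
    "morphometrics": {
        "methods": ["ridge", "skeleton"],
        "sigma": 1.5,
        "low_contrast": 1.5,
        "high_contrast": 4.0,
        "prune_px": 4.0,
    },
    "stats": {
        "alpha": 0.05,
        "df_method": "between_within",
        "variance_fraction": 0.995,
        "transform": True,
    },
    "write_overlays": True,
}


@dataclass
class RunConfig:
    """Validated configuration; ``raw`` holds the fully-defaulted dict."""

    raw: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __getitem__(self, key: str):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])


def _deep_update(base: dict, override: dict) -> dict:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def validate_config(config: dict | None = None) -> RunConfig:
    """Fill defaults and check ranges; raise :class:`ConfigError` on problems."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    if config:
        _deep_update(merged, copy.deepcopy(config))

    seg = merged["segment"]
    for name in ("solidity_cutoff", "overlap_cutoff"):
        v = seg[name]
        if not (0 < v < 1):
            raise ConfigError(f"segment.{name} must be in (0, 1), got {v}")
    if seg["min_area_px"] < 1:
        raise ConfigError("segment.min_area_px must be >= 1")
    for ch, variant in seg["threshold_variant"].items():
        if variant not in ("huang", "huang2"):
            raise ConfigError(f"segment.threshold_variant.{ch}: unknown variant {variant!r}")

    morph = merged["morphometrics"]
    if not (0 <= morph["low_contrast"] < morph["high_contrast"]):
        raise ConfigError("morphometrics: need 0 <= low_contrast < high_contrast")
    for m in morph["methods"]:
        if m not in ("ridge", "skeleton"):
            raise ConfigError(f"morphometrics.methods: unknown method {m!r}")

    st = merged["stats"]
    if not (0 < st["alpha"] < 1):
        raise ConfigError("stats.alpha must be in (0, 1)")
    if st["df_method"] not in ("between_within", "residual"):
        raise ConfigError(f"stats.df_method: unknown {st['df_method']!r}")

    if merged["mode"] not in ("simulate", "manifest"):
        raise ConfigError(f"mode must be simulate or manifest, got {merged['mode']!r}")
    if merged["mode"] == "manifest":
        _validate_manifest(merged)
    else:
        sim = merged["simulation"]
        if sim["n_lines_per_group"] < 1:
            raise ConfigError("simulation.n_lines_per_group must be >= 1")
        if sim["marker"] not in ("MBP", "O4"):
            raise ConfigError("simulation.marker must be MBP or O4")
    return RunConfig(merged)


def _validate_manifest(merged: dict) -> None:
    """One manifest row per channel image: path, group, line, fov, channel."""
    import pandas as pd

    path = merged.get("manifest")
    if not path:
        raise ConfigError("mode=manifest requires a manifest CSV path")
    if not Path(path).exists():
        raise ConfigError(f"manifest not found: {path}")
    mf = pd.read_csv(path)
    required = {"path", "group", "line", "fov", "channel"}
    missing = required - set(mf.columns)
    if missing:
        raise ConfigError(f"manifest missing columns: {sorted(missing)}")
    dupes = mf.duplicated(subset=["line", "fov", "channel"])
    if dupes.any():
        raise ConfigError(f"manifest has duplicate (line, fov, channel) keys at rows "
                          f"{mf.index[dupes].tolist()}")
    problems = []
    for (line, fov), sub in mf.groupby(["line", "fov"]):
        channels = set(sub["channel"])
        if "DAPI" not in channels:
            problems.append(f"({line}, {fov}): missing DAPI")
        if not channels & {"MBP", "O4"}:
            problems.append(f"({line}, {fov}): missing marker channel (MBP or O4)")
    if problems:
        raise ConfigError("manifest channel coverage errors: " + "; ".join(problems))
    for p in mf["path"]:
        if not Path(p).exists():
            raise ConfigError(f"manifest image not found: {p}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return validate_config(doc)
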