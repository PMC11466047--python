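"""Run configuration: a flat, typed YAML schema with strict key checking.

Every parameter is echoed verbatim into output provenance; unknown keys
are rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional

import yaml

from .exceptions import ParameterError

#: allowed keys per section; a top-level scalar section holds run-wide values
SCHEMA: dict[str, set[str]] = {
    "run": {"seed", "output_dir", "log_level", "pixel_um", "input"},
    "lattice": {
        "period_um",
        "aband_um",
        "mline_um",
        "orientation_deg",
        "psf_fwhm_um",
        "pixel_um",
        "shape_px",
        "peak_photons",
        "background_photons",
        "seed",
    },
    "tissue": {
        "n_cardiomyocytes",
        "n_capillaries",
        "cm_radius_um",
        "cm_radius_jitter",
        "cap_radius_um",
        "cap_radius_jitter",
        "fov_um",
        "pixel_um",
        "seed",
        "max_attempts_per_object",
    },
    "sl": {
        "smoothing_um",
        "min_prominence_frac",
        "width_px",
        "sl_bounds_um",
        "otsu_ratio_factor",
        "spacing_cv_threshold",
        "alternation_gap_frac",
        "orientation_sigma_px",
        "exclude_aband",
        "line_px",
    },
    "capquant": {"fov_um2", "exclude_border", "capillary_max_area_um2"},
    "preprocess": {
        "average",
        "gaussian_sigma_um",
        "wiener_window_px",
        "align_reference",
        "binarize_method",
        "binarize_window_px",
        "binarize_offset",
    },
}


def validate_config(cfg: dict[str, Any]) -> dict[str, Any]:
    """Reject unknown sections and keys; return the config unchanged."""
    if not isinstance(cfg, dict):
        raise ParameterError("config root must be a mapping")
    for section, values in cfg.items():
        if section not in SCHEMA:
            raise ParameterError(
                f"unknown config section {section!r}; "
                f"known: {sorted(SCHEMA)}"
            )
        if not isinstance(values, dict):
            raise ParameterError(f"config section {section!r} must be a mapping")
        unknown = set(values) - SCHEMA[section]
        if unknown:
            raise ParameterError(
                f"unknown key(s) {sorted(unknown)} in config section "
                f"{section!r}; known: {sorted(SCHEMA[section])}"
            )
    return cfg


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load and validate a YAML config file; None yields an empty config."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def section(cfg: dict[str, Any], name: str) -> dict[str, Any]:
    return dict(cfg.get(name, {}))


def merged(cfg_section: dict[str, Any], **overrides: Any) -> dict[str, Any]:
    """Config values overridden by explicitly supplied CLI flags."""
    out = dict(cfg_section)
    for k, v in overrides.items():
        if v is not None:
            out[k] = v
    return out


def getseed(cfg: dict[str, Any], cli_seed: Optional[int], default: int = 0) -> int:
    if cli_seed is not None:
        return cli_seed
    return int(section(cfg, "run").get("seed", default))
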