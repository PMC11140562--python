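"""TOML experiment configuration.

All physical quantities are mm / HU / mGy.  Only scalar study parameters
are exposed in the file (seed, repeats, z extent, ROI, dose, preset
overrides); custom phantom geometry is composed through the Python API.
"""

from __future__ import annotations

import tomllib
from dataclasses import replace
from pathlib import Path

from .dose import DoseParams
from .experiment import ExperimentConfig
from .noise import ROISpec
from .recon import reference_presets

_PRESET_FIELDS = {
    "psf_sigma_xy", "psf_sigma_z", "noise_sd_target",
    "nps_shape", "nps_peak_freq", "matrix", "pixel_mm",
}


def load_config(path: str | Path | None = None, seed: int | None = None) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a TOML file (or defaults)."""
    data: dict = {}
    if path is not None:
        data = tomllib.loads(Path(path).read_text())

    presets = reference_presets()
    for entry in data.get("presets", []):
        name = entry.get("name")
        if name not in presets:
            raise ValueError(f"unknown preset {name!r} (have {sorted(presets)})")
        overrides = {k: v for k, v in entry.items() if k in _PRESET_FIELDS}
        presets[name] = replace(presets[name], **overrides)

    kwargs: dict = {"presets": presets}
    for key in ("z_extent_mm", "repeats", "seed"):
        if key in data:
            kwargs[key] = data[key]
    if seed is not None:
        kwargs["seed"] = seed
    if "roi" in data:
        roi = data["roi"]
        kwargs["roi"] = ROISpec(tuple(roi["center"]), tuple(roi["size"]))
    if "dose" in data:
        d = data["dose"]
        kwargs["dose"] = DoseParams(
            d.get("ctdivol", 3.7), d.get("scan_length_mm", 160.0),
            d.get("k_factor", 0.014),
        )
    return ExperimentConfig(**kwargs)
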