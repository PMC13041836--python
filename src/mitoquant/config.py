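"""YAML configuration loading and strict validation for the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AssayConfig", "load_config", "ConfigError", "ASSAYS"]

ASSAYS = (
    "mitoqc_flux",
    "membrane_potential",
    "mito_mass",
    "touching_puncta",
    "lysosome_distribution",
    "nuclear_translocation",
    "dqbsa",
    "cristae",
    "respirometry",
    "simulate",
)

# keys accepted in the top level of an analyze/simulate config
_COMMON_KEYS = {"assay", "seed", "out", "params"}
_ANALYZE_KEYS = _COMMON_KEYS | {
    "input",
    "reference_input",
    "channel_roles",
    "pixel_size_um",
    "plane_order",
    "marker_role",
    "vesicle_role",
    "target_role",
    "area_cutoff_um2",
    "bg_k",
    "min_prominence_frac",
    "min_separation_um",
    "profile_pixel_size_um",
    "po_ratio",
    "o2_per_o",
    "injections",
}
_SIMULATE_KEYS = _COMMON_KEYS | {
    "n_fields",
    "flux_ratio",
    "touching_fraction",
    "n_small",
    "n_depolarized",
    "peripheral_fraction",
    "nuclear_fold",
    "cristae_per_um",
    "length_um",
    "profile_pixel_size_um",
    "noise_sd",
    "levels",
    "n_per_phase",
}
_PARAM_KEYS = {
    # FieldParams
    "field_size_px", "pixel_size_um", "z_slices", "z_step_um", "n_cells",
    "cell_radius_um", "nucleus_radius_um", "mito_segments_per_cell",
    "mito_width_um", "puncta_per_cell", "puncta_radius_um",
    "background_level", "gaussian_sd", "poisson_noise", "seed",
    # PipelineParams
    "tophat_radius_px", "cyto_sigma_px", "watershed_min_seed_px",
    "min_nucleus_area_um2", "gate",
}


class ConfigError(ValueError):
    """Invalid assay configuration."""


@dataclass
class AssayConfig:
    """Validated assay configuration (unknown keys rejected at load time)."""

    assay: str
    raw: dict = field(default_factory=dict)

    def get(self, key, default=None):
        return self.raw.get(key, default)

    @property
    def params(self) -> dict:
        return dict(self.raw.get("params") or {})


def load_config(path: str | Path, mode: str = "analyze") -> AssayConfig:
    """Load and validate a YAML config; raise :class:`ConfigError` on bad keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    assay = raw.get("assay")
    if assay not in ASSAYS:
        raise ConfigError(f"unknown or missing assay {assay!r}; expected one of {ASSAYS}")
    allowed = _SIMULATE_KEYS if mode == "simulate" else _ANALYZE_KEYS
    for key in raw:
        if key not in allowed:
            raise ConfigError(f"unknown config key {key!r}")
    for key in raw.get("params") or {}:
        if key not in _PARAM_KEYS:
            raise ConfigError(f"unknown params key {key!r}")
    return AssayConfig(assay=assay, raw=raw)
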