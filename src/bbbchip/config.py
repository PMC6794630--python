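"""Shared YAML/JSON run-configuration handling for the command line.

A run configuration is a nested mapping with optional sections:

    layout:   {widths_um: {...}, length_um, height_um, barrier_thickness_um, ...}
    imaging:  {gain, background, gaussian_sigma, poisson_enabled,
               pixel_size_um, bit_depth}
    assay:    {solute, p_true_cm_s, frame_interval_s, n_frames,
               luminal_concentration_mol_m3}
    estimator: {fit_mode, window_s, cv_depth_um}
    cohort:   {n_wt, n_ad, p_means_cm_s: {wt, ad}, dispersion}
    simulation: {dx_um, dt_s, scheme, days, snapshot_interval_s}

Missing keys fall back to package defaults. ``--set a.b=value`` overrides use
dotted paths with YAML-parsed values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .geometry import DeviceLayout, build_default_layout
from .imaging import ImagingModel

__all__ = ["load_config", "apply_overrides", "layout_from_config",
           "imaging_model_from_config"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def apply_overrides(config: dict, assignments: Sequence[str]) -> dict:
    """Apply ``key.path=value`` overrides (values parsed as YAML scalars)."""
    out = dict(config)
    for item in assignments:
        if "=" not in item:
            raise ValueError(f"override {item!r} must look like key.path=value")
        path, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        node = out
        keys = path.strip().split(".")
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ValueError(f"cannot descend into non-mapping at {k!r}")
        node[keys[-1]] = value
    return out


def layout_from_config(config: Mapping[str, Any]) -> DeviceLayout:
    section = config.get("layout", {})
    if "regions" in section:  # full explicit layout
        return DeviceLayout.from_dict(section)
    kwargs = {
        k: section[k]
        for k in (
            "widths_um",
            "length_um",
            "height_um",
            "barrier_thickness_um",
            "barrier_diffusivity",
            "region_materials",
        )
        if k in section
    }
    return build_default_layout(**kwargs)


def imaging_model_from_config(config: Mapping[str, Any]) -> ImagingModel:
    section = dict(config.get("imaging", {}))
    return ImagingModel(**section)
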