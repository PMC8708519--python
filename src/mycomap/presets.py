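"""Preset library: per-variant simulation parameters, versioned in YAML.

The packaged ``default_config.yaml`` holds one preset per legal
treatment-phenophase combination, with targets set to the study-level mean
frequency/intensity/arbuscules/vesicles of that variant.  The control point
and the unfertilized variant use the longitudinal strategy, the organically
fertilized variant the radial one.  The ``gap_rate`` and shape knobs were
produced by :func:`mycomap.simulate.calibrate_preset` against those targets
and frozen here.
"""

from __future__ import annotations

from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .core import DesignSpec
from .simulate import StrategyParams

__all__ = ["load_config", "dump_config", "default_config", "default_presets"]

_PACKAGED = "default_config.yaml"


def _combo_key(label: str) -> tuple[str, str]:
    t, _, p = label.partition("-")
    return (t, p)


def load_config(path: str | Path | None = None):
    """Read a YAML config into ``(DesignSpec, presets dict)``.

    ``None`` loads the packaged defaults.  The file has two sections:
    ``design`` (DesignSpec fields) and ``presets`` (mapping of variant
    labels like ``A1-B2`` to StrategyParams fields).
    """
    if path is None:
        text = resources.files(__package__).joinpath(_PACKAGED).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    design_raw = raw.get("design", {}) or {}
    if "combinations" in design_raw:
        design_raw["combinations"] = tuple(
            _combo_key(c) for c in design_raw["combinations"]
        )
    spec = DesignSpec(**design_raw)
    presets = {
        _combo_key(label): StrategyParams(**fields)
        for label, fields in (raw.get("presets", {}) or {}).items()
    }
    return spec, presets


def dump_config(
    spec: DesignSpec,
    presets: Mapping[tuple[str, str], StrategyParams],
    path: str | Path,
) -> None:
    """Write a config round-trippable by :func:`load_config`."""
    payload = {
        "design": {
            "combinations": [f"{t}-{p}" for t, p in spec.combinations],
            "plants_per_combination": spec.plants_per_combination,
            "fragments_per_plant_control": spec.fragments_per_plant_control,
            "fragments_per_plant": spec.fragments_per_plant,
            "fields_per_fragment": spec.fields_per_fragment,
        },
        "presets": {
            f"{t}-{p}": asdict(params) for (t, p), params in presets.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def default_config() -> tuple[DesignSpec, dict]:
    """The packaged design spec and preset library."""
    return load_config(None)


def default_presets() -> dict:
    return default_config()[1]
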