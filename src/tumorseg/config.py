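"""YAML configuration loading for the pipeline CLI.

A config file may contain any of the sections ``model``, ``train``,
``augment``, ``split``, ``phantoms``, ``cbam``; each maps keys directly onto
the corresponding spec dataclass fields.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .attention import CBAMConfig
from .models import ModelConfig
from .phantoms import PhantomSpec
from .pipeline import AugmentSpec, SplitSpec
from .training import TrainConfig

_SECTIONS = {
    "model": ModelConfig,
    "train": TrainConfig,
    "augment": AugmentSpec,
    "split": SplitSpec,
    "phantoms": PhantomSpec,
}


def _build(cls, mapping):
    if mapping is None:
        mapping = {}
    if cls is ModelConfig and "cbam" in mapping:
        mapping = dict(mapping)
        mapping["cbam"] = CBAMConfig(**mapping["cbam"])
    for key in ("decoder_widths", "tumor_semi_axes_range", "fixed_rotations"):
        if key in mapping and mapping[key] is not None:
            mapping = dict(mapping)
            mapping[key] = tuple(mapping[key])
    return cls(**mapping)


def load_config(path):
    """Parse a YAML file into a dict of validated spec objects."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            obj = _build(cls, raw[name])
            if hasattr(obj, "validate"):
                obj.validate()
            out[name] = obj
    return out
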