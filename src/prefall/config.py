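"""YAML/JSON configuration for the command-line interface.

A config file mirrors the pipeline's parameter objects, e.g.::

    gait:
      preset: shank          # or explicit SyntheticGaitConfig fields
      noise_sd_rad: 0.01
    perturbation:
      mode: arrest
      onset_s: 15.0
    ao: {k_P: 20, k_A: 1}
    atba: {w: 400, k: 3.5, r: 6}
    grid:
      kP_values: [1, 10, 20]
    fa_threshold_pct: 10.0
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Union

import yaml

from .detector import ATBAParams
from .oscillator import AOParams
from .pipeline import TuningGrid
from .synthetic import PerturbationConfig, SyntheticGaitConfig, preset_config

__all__ = [
    "load_config",
    "gait_from_dict",
    "perturbation_from_dict",
    "ao_from_dict",
    "atba_from_dict",
    "grid_from_dict",
    "config_hash",
]


def gait_from_dict(d: dict) -> SyntheticGaitConfig:
    d = dict(d)
    preset = d.pop("preset", None)
    if "harmonics" in d:
        d["harmonics"] = tuple(tuple(h) for h in d["harmonics"])
    if preset is not None:
        return preset_config(preset, **d)
    return SyntheticGaitConfig(**d)


def perturbation_from_dict(d: dict) -> PerturbationConfig:
    return PerturbationConfig(**d)


def ao_from_dict(d: dict) -> AOParams:
    return AOParams(**d)


def atba_from_dict(d: dict) -> ATBAParams:
    return ATBAParams(**d)


def grid_from_dict(d: dict) -> TuningGrid:
    return TuningGrid(**{k: tuple(v) for k, v in d.items()})


_SECTION_BUILDERS = {
    "gait": gait_from_dict,
    "perturbation": perturbation_from_dict,
    "ao": ao_from_dict,
    "atba": atba_from_dict,
    "grid": grid_from_dict,
}


def load_config(path: Union[str, Path]) -> dict:
    """Parse a YAML (or JSON) config file into parameter objects.

    Returns a dict holding only the sections present in the file, with
    values converted to the corresponding dataclasses; scalar entries
    (e.g. ``fa_threshold_pct``, ``seed``) pass through unchanged.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    out: dict[str, Any] = {}
    for key, value in raw.items():
        builder = _SECTION_BUILDERS.get(key)
        out[key] = builder(value) if builder else value
    return out


def config_hash(obj: Any) -> str:
    """Short stable hash of a (possibly dataclass-bearing) config object,
    recorded in run logs for reproducibility."""

    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
        if hasattr(o, "tolist"):
            return o.tolist()
        return repr(o)

    blob = json.dumps(obj, default=enc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
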