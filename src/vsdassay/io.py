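"""Config parsing and result serialization for the command-line pipeline.

Run configurations are YAML (or JSON, a YAML subset) documents with
per-module blocks; every block is validated through the corresponding
dataclass constructor before any computation starts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .field import CultureGeometry, Electrode, StimulusPulse
from .imaging import DyeModel
from .membrane import KKinetics, NaKinetics, PassiveMembrane, StimProtocol

__all__ = [
    "load_config",
    "config_hash",
    "membrane_from_config",
    "na_from_config",
    "kdr_from_config",
    "protocol_from_config",
    "geometry_from_config",
    "pulse_from_config",
    "dye_from_config",
    "write_json",
]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} did not parse to a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, recorded in run logs."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, block: dict | None, what: str):
    block = block or {}
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigurationError(f"invalid {what} block: {exc}") from exc


def membrane_from_config(cfg: dict) -> PassiveMembrane:
    return _build(PassiveMembrane, cfg.get("membrane"), "membrane")


def na_from_config(cfg: dict) -> NaKinetics | None:
    if "kinetics" not in cfg or cfg["kinetics"] is None:
        return None
    return _build(NaKinetics, cfg["kinetics"], "kinetics")


def kdr_from_config(cfg: dict) -> KKinetics | None:
    if "delayed_rectifier" not in cfg or cfg["delayed_rectifier"] is None:
        return None
    return _build(KKinetics, cfg["delayed_rectifier"], "delayed_rectifier")


def protocol_from_config(cfg: dict) -> StimProtocol:
    return _build(StimProtocol, cfg.get("protocol"), "protocol")


def pulse_from_config(cfg: dict) -> StimulusPulse:
    return _build(StimulusPulse, cfg.get("pulse"), "pulse")


def dye_from_config(cfg: dict) -> DyeModel:
    return _build(DyeModel, cfg.get("dye"), "dye")


def geometry_from_config(cfg: dict) -> CultureGeometry:
    block = cfg.get("geometry")
    if block is None:
        raise ConfigurationError("config has no geometry block")
    electrodes = [Electrode(center=tuple(e["center"]), radius=e.get("radius", 0.025),
                            polarity=e["polarity"]) for e in block.get("electrodes", [])]
    cells = [np.asarray(c, dtype=float) for c in block.get("cells", [])]
    return CultureGeometry(domain=np.asarray(block["domain"], dtype=float),
                           electrodes=electrodes, cells=cells)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
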