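"""Plain-text configuration and run manifests.

Parameter sets are serialized as YAML key-value files whose keys match the
dataclass field names exactly; unknown keys are rejected so that typos
fail loudly.  Every CLI command writes a manifest tying its outputs to a
config hash and seed, sufficient to re-run the command bit-identically
(deterministic commands) or distribution-identically (stochastic ones).
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import os
import time
from dataclasses import dataclass, field, fields

import yaml

from .params import DecoupledParams, DetailedParams, Params, ReducedParams

__all__ = ["load_config", "save_config", "params_from_dict", "params_to_dict",
           "default_params", "RunManifest"]

_DETAILED_ONLY = {f.name for f in fields(DetailedParams)} - {f.name for f in fields(ReducedParams)}
_DECOUPLED_ONLY = {f.name for f in fields(DecoupledParams)} - {f.name for f in fields(ReducedParams)}


def load_config(path) -> dict:
    """Load a YAML config file into a dict (must be a mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    _atomic_write(path, yaml.safe_dump(cfg, sort_keys=True))


def params_from_dict(d: dict) -> Params:
    """Build a parameter set from a plain mapping, rejecting unknown keys.

    The class is chosen from the keys present: decoupled-only fields
    (``Q_tot`` etc.) select :class:`DecoupledParams`, detailed-only fields
    select :class:`DetailedParams`, otherwise :class:`ReducedParams`.
    """
    keys = set(d)
    if keys & {"Q_tot", "k_cons"}:
        cls = DecoupledParams
    elif keys & _DETAILED_ONLY:
        cls = DetailedParams
    else:
        cls = ReducedParams
    valid = {f.name for f in fields(cls)}
    unknown = keys - valid
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    try:
        return cls(**d)
    except ValueError as exc:
        raise ValueError(f"invalid parameter value: {exc}") from exc


def params_to_dict(p: Params) -> dict:
    return dataclasses.asdict(p)


def default_params(name: str) -> Params:
    """Load one of the packaged default parameter sets.

    Available names: wild_type, t281r, t281r_dp2, detailed_wt,
    detailed_t281r, decoupled_low_kd, decoupled_high_kd.
    """
    ref = importlib.resources.files("tcswitch") / "configs" / f"{name}.yaml"
    if not ref.is_file():
        raise ValueError(f"no packaged parameter set named {name!r}")
    return params_from_dict(yaml.safe_load(ref.read_text()))


def _atomic_write(path, text: str) -> None:
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written alongside every command's outputs."""

    command: str
    config: dict
    seed: int | None
    outputs: list = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def finalize(self):
        from . import __version__
        self.version = __version__
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def write(self, path) -> None:
        self.finalize()
        doc = dataclasses.asdict(self)
        doc["config_hash"] = config_hash(self.config)
        _atomic_write(path, json.dumps(doc, indent=2, default=str))
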