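"""YAML configuration: chain roles, domain/helix definitions, cutoffs.

The shipped defaults reproduce the standard troponin-core bookkeeping —
TnC 1-161, TnI 1-169, TnT 202-288 — with NcTnC = TnC 1-85, hinge linker
TnC 86-92, ITC = TnC 93-161 plus the TnI IT-arm helices, helix A = TnC
14-28 and helix B = TnC 41-48.  These ranges are defaults, override per
study: domain and helix boundaries are user-declared, never detected.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .geometry import DomainDefinition, HelixDefinition, HingeDefinition

__all__ = ["ConfigError", "default_config", "load_config", "validate_config",
           "hinge_from_config", "helices_from_config"]


class ConfigError(ValueError):
    """Invalid or incomplete configuration."""


_DEFAULT_CONFIG = {
    "chains": {"C": "TnC", "I": "TnI", "T": "TnT", "L": "ligand"},
    "domains": {
        "NcTnC": [["TnC", [1, 85]]],
        "ITC": [["TnC", [93, 161]], ["TnI", [43, 79]], ["TnI", [90, 135]]],
        "linker": ["TnC", [86, 92]],
    },
    "helices": {"A": ["TnC", [14, 28]], "B": ["TnC", [41, 48]]},
    "cutoffs": {"contact": 2.5, "ionic_bond": 4.0},
    "histogram": {"bin_width": 1.0, "thresholds": [110.0]},
    "cluster": {"eps": 10.0, "min_frac": 0.01, "reference_frame": 0},
    "dose": {"ca_single_point_uM": 0.075, "uncoupled_threshold": 5.0},
    # Synthetic study conditions for `run-all`: a wild-type pair whose hinge
    # angle rises and A/B angle falls on phosphorylation, and a mutant pair
    # with the opposite hinge response and a persistently occupied D159-K83
    # bond; 400 frames per condition.
    "conditions": [
        {"genotype": "WT", "phospho": "uP", "ligand": "7r",
         "hinge_mean": 118.0, "hinge_sigma": 8.0, "ab_angle": ["normal", 112.0, 5.0],
         "n_frames": 400, "bond_occupancy_target": 0.60},
        {"genotype": "WT", "phospho": "SEP", "ligand": "7r",
         "hinge_mean": 124.0, "hinge_sigma": 8.0, "ab_angle": ["normal", 106.0, 5.0],
         "n_frames": 400, "bond_occupancy_target": 0.20},
        {"genotype": "G159D", "phospho": "uP", "ligand": "7r",
         "hinge_mean": 122.0, "hinge_sigma": 8.0, "ab_angle": ["normal", 106.0, 5.0],
         "n_frames": 400, "bond_occupancy_target": 0.80},
        {"genotype": "G159D", "phospho": "SEP", "ligand": "7r",
         "hinge_mean": 119.0, "hinge_sigma": 8.0, "ab_angle": ["normal", 111.0, 5.0],
         "n_frames": 400, "bond_occupancy_target": 0.78},
    ],
}

_REQUIRED_KEYS = ("chains", "domains", "helices")


def default_config() -> dict:
    return copy.deepcopy(_DEFAULT_CONFIG)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the defaults (shallow, per top key)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    missing = [k for k in _REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ConfigError(f"config missing required keys: {missing}")
    for key in _REQUIRED_KEYS:
        if not isinstance(cfg[key], dict):
            raise ConfigError(f"config {key!r} must be a mapping")
    domains = cfg["domains"]
    for key in ("NcTnC", "ITC", "linker"):
        if key not in domains:
            raise ConfigError(f"config 'domains' missing {key!r}")
    for key in ("A", "B"):
        if key not in cfg["helices"]:
            raise ConfigError(f"config 'helices' missing helix {key!r}")


def _parts(raw) -> tuple:
    return tuple((role, (int(lo), int(hi))) for role, (lo, hi) in raw)


def hinge_from_config(cfg: dict) -> HingeDefinition:
    d = cfg["domains"]
    role, (lo, hi) = d["linker"]
    return HingeDefinition(
        domain1=DomainDefinition("NcTnC", _parts(d["NcTnC"])),
        domain2=DomainDefinition("ITC", _parts(d["ITC"])),
        linker=(role, (int(lo), int(hi))),
    )


def helices_from_config(cfg: dict) -> tuple[HelixDefinition, HelixDefinition]:
    out = []
    for label in ("A", "B"):
        role, (lo, hi) = cfg["helices"][label]
        out.append(HelixDefinition(label=label, role=role, first=int(lo), last=int(hi)))
    return tuple(out)
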