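"""Run configuration: one YAML document with a section per pipeline stage.

Every default of the package is encoded in :data:`DEFAULT_CONFIG`; a user
YAML overrides keys selectively.  Unknown keys are rejected so typos fail
at validation time, and the resolved configuration is hashed into the run
manifest for cache invalidation and provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "config_hash"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_sites": 36,
        "n_species": 113,
        "n_juvenile_species": 47,
        "n_corals": 8,
        "cover": {},          # CoverConfig overrides
        "community": {},      # CommunityHyperparams overrides
        "occasions": {"mean": 4.84, "sd": 2.56},
    },
    "prepare": {
        "min_sites": 4,       # coral inclusion rule: non-zero cover in >= N sites
        "unresolved_species": [],
    },
    "fit": {
        "corals": None,       # None: every coral passing the inclusion rule
        "stages": ["adult", "juvenile"],
        "n_chains": 3,
        "n_saved_per_chain": 1000,
        "warmup": 2000,
        "pooling": "hierarchical",
        "plot_effect": True,
        "shared_detection": False,
        "ci_levels": [0.90, 0.50],
        "compute_bpv": True,
        "bpv_draws": 500,
        "save_draws": False,
    },
    "classify": {
        "ci_level": 0.90,
        "turf_rule": "mean",
    },
    "traitspace": {
        "trait_set": "six",   # or "four": group size, max body size, trophic level, aspect ratio
        "n_axes": 2,
        "correction": "cailliez",
    },
    "scenarios": {
        "n_runs": 100,
        "vertex_weight": 10.0,
        "refresh_vertices": True,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and key not in ("cover", "community", "occasions"):
            if not isinstance(val, dict):
                raise ValueError(f"{here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(cfg: dict) -> None:
    sim = cfg["simulate"]
    if sim["n_sites"] < 2:
        raise ValueError("simulate.n_sites must be >= 2")
    if sim["n_species"] < 4:
        raise ValueError("simulate.n_species must be >= 4")
    if not 0 <= sim["n_juvenile_species"] <= sim["n_species"]:
        raise ValueError("simulate.n_juvenile_species out of range")
    fit = cfg["fit"]
    if fit["n_chains"] < 1:
        raise ValueError("fit.n_chains must be >= 1")
    if fit["pooling"] not in ("hierarchical", "fixed"):
        raise ValueError("fit.pooling must be 'hierarchical' or 'fixed'")
    for stage in fit["stages"]:
        if stage not in ("adult", "juvenile"):
            raise ValueError(f"unknown life stage {stage!r}")
    if cfg["traitspace"]["trait_set"] not in ("six", "four") and not isinstance(
        cfg["traitspace"]["trait_set"], (list, tuple)
    ):
        raise ValueError("traitspace.trait_set must be 'six', 'four' or a list")
    if cfg["scenarios"]["vertex_weight"] < 1:
        raise ValueError("scenarios.vertex_weight must be >= 1")
    if not 0 < cfg["classify"]["ci_level"] < 1:
        raise ValueError("classify.ci_level must be in (0, 1)")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve defaults <- YAML file <- in-memory overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
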