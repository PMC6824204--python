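"""Configuration, artifact serialization, seed plumbing and the setup bundle.

All structured artifacts (plant, sensory maps, phoneme inventory) serialize to
a single JSON container with a payload checksum; floats go through Python's
repr so a save/load round-trip is bit-exact.  One master seed deterministically
spawns every component seed (plant build, map fit, target derivation, per-chain
sampling) through :func:`derive_seed`.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .internal_models import SensoryMap, fit_sensory_map
from .plant import Plant
from .targets import PhonemeInventory, build_inventory

FORMAT_VERSION = 1

_ARTIFACT_TYPES = {
    "Plant": Plant,
    "SensoryMap": SensoryMap,
    "PhonemeInventory": PhonemeInventory,
}


class IntegrityError(RuntimeError):
    """An artifact file failed its checksum or version check."""


def derive_seed(master: int, *tokens) -> int:
    """Stable sub-seed (< 2^31) from a master seed and labelling tokens."""
    h = hashlib.sha256(("/".join(map(str, (master, *tokens)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# --------------------------------------------------------------------- bundle
@dataclass
class Setup:
    """Plant + fitted internal models + phoneme inventory, built consistently."""

    plant: Plant
    maps: dict[str, SensoryMap]
    inventory: PhonemeInventory
    _scales: dict = field(default_factory=dict)

    def sensory_scale(self, modality: str) -> float:
        """RMS per-dimension corpus standard deviation of one sensory space.

        Used as the unit anchor when soft-match widths η are specified as
        fractions of the space's natural spread.
        """
        if modality not in self._scales:
            M = self.plant.sample_controls(2000, seed=derive_seed(self.plant.seed, "scale"))
            X = self.plant.auditory(M) if modality == "auditory" else self.plant.somato(M)
            self._scales[modality] = float(np.sqrt((X.std(axis=0) ** 2).mean()))
        return self._scales[modality]


def build_setup(
    seed: int = 0,
    n_train: int = 50000,
    n_pca: int = 5000,
    n_centers: int = 800,
    bandwidth: float | None = None,
    n_derive: int = 5000,
    derive_chains: int = 10,
    derive_burn: int = 500,
) -> Setup:
    """Build the whole modelling stack from one master seed.

    Scaled-down sizes (smaller ``n_train``/``n_centers``/``n_derive``) trade
    internal-model fidelity for speed; the defaults match the full study
    conditions (a ~50k-sample training corpus for the sensory-motor maps).
    """
    plant = Plant.build(seed=derive_seed(seed, "plant"), n_pca=n_pca)
    M = plant.sample_controls(n_train, seed=derive_seed(seed, "corpus"))
    A, S = plant.auditory(M), plant.somato(M)
    maps = {
        "auditory": fit_sensory_map(
            M, A, "auditory", plant.bounds, n_centers=n_centers,
            bandwidth=bandwidth, seed=derive_seed(seed, "map", "auditory"),
        ),
        "somatosensory": fit_sensory_map(
            M, S, "somatosensory", plant.bounds, n_centers=n_centers,
            bandwidth=bandwidth, seed=derive_seed(seed, "map", "somatosensory"),
        ),
    }
    inventory = build_inventory(
        plant, maps, seed=derive_seed(seed, "targets"),
        n_derive=n_derive, chains=derive_chains, burn=derive_burn,
    )
    return Setup(plant=plant, maps=maps, inventory=inventory)


# ------------------------------------------------------------------ artifacts
def _payload_checksum(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def save_artifact(obj, path) -> str:
    """Write a serializable object as a checksummed JSON container."""
    payload = obj.to_dict()
    container = {
        "format_version": FORMAT_VERSION,
        "checksum": _payload_checksum(payload),
        "payload": payload,
    }
    path = Path(path)
    path.write_text(json.dumps(container))
    return container["checksum"]


def load_artifact(path, expected_type: str | None = None):
    """Load an artifact, verifying version, checksum and (optionally) type."""
    container = json.loads(Path(path).read_text())
    if container.get("format_version") != FORMAT_VERSION:
        raise IntegrityError(f"unsupported artifact version {container.get('format_version')!r}")
    payload = container["payload"]
    if _payload_checksum(payload) != container.get("checksum"):
        raise IntegrityError(f"checksum mismatch in {path}")
    kind = payload.get("type")
    if expected_type is not None and kind != expected_type:
        raise IntegrityError(f"expected a {expected_type} artifact, found {kind!r}")
    try:
        cls = _ARTIFACT_TYPES[kind]
    except KeyError:
        raise IntegrityError(f"unknown artifact type {kind!r}") from None
    return cls.from_dict(payload)


# --------------------------------------------------------------------- config
CONFIG_DEFAULTS = {
    "seed": 0,
    "phoneme": "ɔ",
    "modes": ["auditory", "somatosensory", "fusion"],
    "perturbation": {"delta": [-100.0, 0.0, 0.0]},
    "plant": {"n_pca": 5000},
    "maps": {"n_train": 50000, "n_centers": 800, "bandwidth": None, "ridge": 1e-8},
    "targets": {"n_derive": 5000, "chains": 10, "burn": 500},
    "sampler": {
        "chains": 20,
        "burn": 1000,
        "draws": 1000,
        "proposal_scale": 0.05,
        "target_accept": 0.23,
        "adapt_interval": 50,
        "init_probes": 200,
    },
    "preference": {"mode": "none", "kappa_a": 1.0, "kappa_s": 1.0, "eta_a": 0.0, "eta_s": 0.0},
    "sweep": {"param": "kappa_a", "grid": None},
}


class ConfigError(ValueError):
    """A configuration file contains unknown keys or ill-typed values."""


def _merge(defaults, given, trail=""):
    if not isinstance(given, dict):
        raise ConfigError(f"expected a mapping at {trail or 'top level'}")
    out = {}
    for key, dval in defaults.items():
        if key in given:
            gval = given[key]
            if isinstance(dval, dict):
                out[key] = _merge(dval, gval, f"{trail}{key}.")
            else:
                out[key] = gval
        else:
            out[key] = json.loads(json.dumps(dval))  # deep copy
    for key in given:
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {trail}{key!r}")
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML (or JSON) configuration, fill defaults, reject unknown keys."""
    given = {}
    if path is not None:
        text = Path(path).read_text()
        given = yaml.safe_load(text) or {}
    cfg = _merge(CONFIG_DEFAULTS, given)
    if overrides:
        cfg = _merge(cfg, {**{k: cfg[k] for k in cfg}, **overrides})
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


# ------------------------------------------------------------------- manifest
@dataclass
class RunManifest:
    """Reproducibility record written by every CLI invocation."""

    command: str
    config: dict
    seeds: dict
    artifacts: dict            # name -> {"path": ..., "checksum": ...}
    timestamp: float = field(default_factory=time.time)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config_hash": config_hash(self.config),
            "config": self.config,
            "seeds": self.seeds,
            "artifacts": self.artifacts,
            "timestamp": self.timestamp,
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
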