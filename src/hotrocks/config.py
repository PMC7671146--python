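"""Shared configuration and master-seed management.

A single YAML file parameterizes every stage (rock field, tide model,
microclimate calibration, trait coefficients, metabolic coefficients, IBM
settings).  :func:`load_config` returns the packaged defaults, deep-merged
with an optional user file.  All stochastic stages draw their seeds through
:func:`seed_for`, which derives an independent, reproducible substream from
a master seed and a stable text label.
"""

from __future__ import annotations

import copy
import zlib
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = ["load_config", "default_config", "deep_merge", "seed_for", "rng_for"]


def _packaged_defaults() -> dict:
    ref = resources.files("hotrocks.data").joinpath("default_config.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def default_config() -> dict:
    """Return a fresh copy of the packaged default configuration."""
    return copy.deepcopy(_packaged_defaults())


def deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict:
    """Recursively merge ``override`` into ``base`` (override wins)."""
    merged = dict(copy.deepcopy(base))
    for key, value in override.items():
        if (
            key in merged
            and isinstance(merged[key], Mapping)
            and isinstance(value, Mapping)
        ):
            merged[key] = deep_merge(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def load_config(path: str | Path | None = None) -> dict:
    """Load the effective configuration.

    Parameters
    ----------
    path
        Optional user YAML file; its keys override the packaged defaults
        block-by-block.
    """
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file must contain a mapping: {path}")
    return deep_merge(cfg, user)


def seed_for(master_seed: int, label: str) -> int:
    """Derive a deterministic 31-bit child seed from a master seed + label.

    The label is hashed with CRC-32 so the mapping is stable across runs and
    Python processes (``hash()`` is salted and unsuitable).
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    """A ``numpy`` Generator on the substream named by ``label``."""
    return np.random.default_rng(seed_for(master_seed, label))
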