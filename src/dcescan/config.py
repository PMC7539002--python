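"""Run configuration, defaults and the reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import yaml

from . import __version__

__all__ = ["DEFAULTS", "load_config", "RunManifest"]

#: Full default configuration; YAML files override keys selectively.
DEFAULTS: dict = {
    "bin_size": 10_000,
    "assignment": "overlap",         # gene-to-bin: overlap | tss
    "length_mode": "span",
    "scale": 1000,                   # length normalization unit (bp per unit)
    "w": 3,                          # window size, bins
    "threshold": 0.25,               # bin-signal threshold
    "alpha": 0.05,                   # boundary-test significance
    "mask_alpha": 0.05,              # correlation-mask significance
    "n_perm": 1000,
    "two_sided": True,
    "min_size": 2,                   # bins, smallest testable domain
    "max_missing_gap": 2,            # bins, largest bridgeable missing run
    "intact_jaccard": 0.8,
    "min_overlap_frac": 0.0,
    "seed": 0,
}


def load_config(path: str | None = None, **overrides) -> dict:
    """DEFAULTS merged with an optional YAML file and keyword overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    stage: str
    config: dict
    seed: int | None = None
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)   # record counts per artifact
    version: str = __version__
    started: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_input(self, path: str) -> None:
        self.inputs[path] = _digest(path)

    def add_output(self, path: str) -> None:
        self.outputs[path] = _digest(path)

    def time_stage(self, name: str, seconds: float, n_records: int | None = None) -> None:
        self.timings[name] = round(seconds, 3)
        if n_records is not None:
            self.counts[name] = n_records

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
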