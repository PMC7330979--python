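"""One place for every tunable threshold, with a declarative YAML override.

Every published constant the pipeline uses is greppable here and can be
overridden from a config file; unknown keys are rejected by name.
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULTS = {
    # database-side interaction cutoffs, Å
    "hb_cutoff": 3.50,
    "ionic_cutoff": 6.00,
    "disulfide_cutoff": 2.08,
    # target pair enumeration
    "ca_min": 3.35,
    "ca_max": 16.40,
    "min_seq_separation": 3,
    # search gates
    "rmsd_threshold": 0.5,
    "clash_cutoff": 2.0,
    "region_radius": 10.0,
    # database construction
    "cluster_cutoff": 0.5,
    # signatures
    "sig_d_min": 0.0,
    "sig_d_max": 10.0,
    "sig_step": 0.1,
    "energy_fraction": 0.70,
    "svd_criterion": "singular",
    # signature pre-filter: inf disables; 13.0 is the full-scale calibration
    "ssv_cutoff": math.inf,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """DEFAULTS, optionally updated from a YAML file and a dict. Unknown keys
    raise :class:`ConfigError` naming the key."""
    cfg = dict(DEFAULTS)
    layers = []
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        layers.append(data)
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for key, value in layer.items():
            if key not in cfg:
                raise ConfigError(f"unknown configuration key {key!r}")
            if key == "ssv_cutoff" and value in ("inf", ".inf", None):
                value = math.inf
            cfg[key] = value
    return cfg
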