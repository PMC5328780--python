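"""Model configuration: all conductances, thresholds and gains, YAML-backed.

Conductance keys follow the network's published symbol names where those
exist: ``g_app3``/``g_app4`` are the central drives to the front leg's
levator/depressor CPG neurons (C3/C4), ``g_app9``/``g_app10`` the middle
leg's (C9/C10), ``g_app15``/``g_app16`` the hind leg's (C15/C16);
``g_inh3``/``g_inh9`` are the maximal conductances of the intersegmental
synapses onto C3 and C9; ``g_MN`` is the uniform excitatory input to all
motoneurons and ``g_d0`` the default inhibitory input to every premotor
interneuron (individually overridable, e.g. g_d5/g_d6 on the front leg's
levator/depressor premotor INs, IN29/IN30 on the hind leg's).

The committed ``data/baseline.yaml`` is the calibrated reference
configuration: its two mode tables yield the target stepping periods
(tetrapod ≈ 1180 ms, tripod ≈ 615 ms).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Dict

import yaml

MODES = ("tetrapod", "tripod")
LD_DRIVE_KEYS = {
    "FL": ("g_app3", "g_app4"),
    "ML": ("g_app9", "g_app10"),
    "HL": ("g_app15", "g_app16"),
}


class ConfigError(KeyError):
    """A required configuration key is missing or invalid."""


@dataclass
class ModelConfig:
    """Nested-dict configuration with validated access."""
    data: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ModelConfig":
        with resources.files("stickwalk.data").joinpath("baseline.yaml").open() as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(self.data, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def get(self, *keys, default=None):
        d = self.data
        for k in keys:
            if not isinstance(d, dict) or k not in d:
                return default
            d = d[k]
        return d

    def require(self, *keys):
        d = self.data
        for k in keys:
            if not isinstance(d, dict) or k not in d:
                raise ConfigError(f"missing configuration key: {'.'.join(map(str, keys))}")
            d = d[k]
        return d

    def copy(self) -> "ModelConfig":
        return ModelConfig(copy.deepcopy(self.data))

    def updated(self, dotted_key: str, value) -> "ModelConfig":
        """Return a copy with one dotted key replaced (e.g.
        ``modes.tetrapod.g_app15``)."""
        cfg = self.copy()
        keys = dotted_key.split(".")
        d = cfg.data
        for k in keys[:-1]:
            d = d.setdefault(k, {})
        d[keys[-1]] = value
        return cfg

    # -- convenience accessors -------------------------------------------
    @property
    def mode(self) -> str:
        return self.get("mode", default="tetrapod")

    def mode_drives(self, mode: str) -> Dict[str, float]:
        if mode not in MODES:
            raise ConfigError(f"unknown coordination mode: {mode!r}")
        tab = self.require("modes", mode)
        for leg, (klev, kdep) in LD_DRIVE_KEYS.items():
            for key in (klev, kdep):
                if key not in tab:
                    raise ConfigError(f"missing configuration key: modes.{mode}.{key}")
        return tab
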