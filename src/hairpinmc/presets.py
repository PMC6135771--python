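"""Packaged model presets and literature reference data.

Three presets per model family emulate the three hairpin folding regimes:

* ``GB1p-like`` — flexible loop, strong hydrophobic contacts: cooperative
  two-state folding with a large entropic cost;
* ``HP5A-like`` — rigidified loop, weakened contacts: marginally stable
  two-state folder with a small entropic cost;
* ``GB1m3-like`` — rigidified loop, strong contacts: folded-state dominated,
  essentially downhill folding at low temperature.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .cgmodel import CGParameters
from .constants import R_KCAL
from .topology import Topology, build_hairpin_topology
from .zipper import ZipperModel

__all__ = [
    "PRESET_NAMES",
    "load_zipper_preset",
    "load_cg_preset",
    "load_reference",
]

PRESET_NAMES = ("GB1p-like", "HP5A-like", "GB1m3-like")


def _load_yaml(name: str) -> dict:
    with resources.files("hairpinmc.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _presets() -> dict:
    return _load_yaml("presets.yaml")


def power_law_degeneracy(n_bonds: int, s0: float, gamma: float) -> np.ndarray:
    """Degeneracy ladder ``Omega(N) = exp(s0 (1 - (N/n)^gamma))``."""
    n = np.arange(n_bonds + 1)
    return np.exp(s0 * (1.0 - (n / n_bonds) ** gamma))


def load_zipper_preset(name: str) -> ZipperModel:
    """Zipper model for a preset name, in physical units (kcal/mol, K)."""
    presets = _presets()["zipper"]
    if name not in presets:
        raise ValueError(f"unknown zipper preset {name!r}; valid: {sorted(presets)}")
    p = presets[name]
    return ZipperModel(
        n_bonds=int(p["n_bonds"]),
        epsilon=float(p["epsilon"]),
        degeneracy=power_law_degeneracy(int(p["n_bonds"]), float(p["s0"]), float(p["gamma"])),
        kb=R_KCAL,
    )


def load_cg_preset(name: str) -> tuple[Topology, CGParameters]:
    """Topology and coarse-grained parameters for a preset name."""
    presets = _presets()["cg"]
    if name not in presets:
        raise ValueError(f"unknown CG preset {name!r}; valid: {sorted(presets)}")
    p = dict(presets[name])
    topology = build_hairpin_topology(p.pop("sequence"))
    return topology, CGParameters(**p)


def load_reference() -> dict:
    """Literature reference values (populations, 270 K thermodynamics and
    the energy-component decomposition) for the three hairpins."""
    return _load_yaml("reference.yaml")
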