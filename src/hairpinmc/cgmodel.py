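"""Coarse-grained hairpin energy model and Monte Carlo move set.

The model is a native-centric (Go-like) potential over the CA trace with
surrogate O/HN/SC beads supplying the literal distance criteria used by the
analysis layer.  Energy terms (all in kcal/mol):

``bonded``
    Harmonic CA-CA bonds, harmonic CA angles and a weak cosine dihedral.
    Within the loop segment (residues between ``topology.loop_residues``)
    the angle/dihedral terms are restrained to the native turn geometry and
    scaled by the dimensionless loop-stiffness multiplier ``lambda_loop``;
    a proline-rigidified loop corresponds to a large multiplier, the
    flexible wild-type loop to a small one.
``excluded_volume``
    Soft-core repulsion between CA beads separated by two or more bonds.
    Finite at zero separation by construction.
``hbond_contact``
    Attractive switched wells between the seven native HN/O surrogate-bead
    pairs; full depth ``eps_hb`` inside ``hb_r_on`` (chosen to enclose the
    2.6 A counting criterion), switching smoothly to zero at ``hb_r_off``.
``sidechain_contact``
    Same functional form for the two native side-chain pairs with depth
    ``eps_sc``.
``screened_charge``
    Optional Debye-screened Coulomb term between charged residues
    (K/R = +1, D/E = -1), off by default.

The MC state is the (n_residues, 3) CA coordinate array; surrogate beads
are re-derived after every move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import R_KCAL
from .frame import Frame
from .geometry import (
    extended_ca_coordinates,
    native_ca_coordinates,
    place_surrogate_beads,
)
from .topology import Topology

__all__ = [
    "CGParameters",
    "HairpinModel",
    "cg_energy",
    "build_native_fixture",
    "build_extended_fixture",
]

ENERGY_TERMS = (
    "bonded",
    "excluded_volume",
    "hbond_contact",
    "sidechain_contact",
    "screened_charge",
)

_RESIDUE_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


@dataclass
class CGParameters:
    """Tunable parameters of the coarse-grained hairpin potential."""

    # bonded terms
    bond_k: float = 20.0            # kcal/mol/A^2
    bond_r0: float = 3.8            # A
    angle_k: float = 1.5            # kcal/mol/rad^2, generic angle prior
    angle_theta0_deg: float = 143.0  # pleated-strand CA angle
    dihedral_k: float = 0.2         # kcal/mol, generic cosine dihedral
    loop_angle_k: float = 4.0       # kcal/mol/rad^2, native-turn restraint (x lambda_loop)
    loop_dihedral_k: float = 2.0    # kcal/mol/rad^2 (x lambda_loop)
    lambda_loop: float = 1.0        # dimensionless loop-stiffness multiplier
    # excluded volume (soft core, finite at zero separation)
    excluded_sigma: float = 2.5     # A
    excluded_epsilon: float = 1.0   # kcal/mol
    # native-contact wells
    eps_hb: float = 1.0             # kcal/mol per H-bond pair
    hb_r_on: float = 2.6            # A, full-depth radius
    hb_r_off: float = 5.5           # A, well extinction radius
    eps_sc: float = 1.5             # kcal/mol per side-chain pair
    sc_r_on: float = 5.0            # A
    sc_r_off: float = 8.0           # A
    # optional screened charges
    charge_strength: float = 0.0    # kcal/mol * A per unit charge product
    debye_length: float = 8.0       # A

    def __post_init__(self) -> None:
        if self.eps_hb < 0 or self.eps_sc < 0:
            raise ValueError("contact well depths must be non-negative")
        if self.lambda_loop <= 0:
            raise ValueError("lambda_loop must be positive")
        for name in ("hb", "sc"):
            r_on = getattr(self, f"{name}_r_on")
            r_off = getattr(self, f"{name}_r_off")
            if not 0 < r_on < r_off:
                raise ValueError(f"need 0 < {name}_r_on < {name}_r_off")

    def with_overrides(self, **kwargs) -> "CGParameters":
        return replace(self, **kwargs)


def _switch(d: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """Smooth switching function: 1 below r_on, 0 above r_off."""
    s = np.clip((d - r_on) / (r_off - r_on), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * s))


def _angles(ca: np.ndarray) -> np.ndarray:
    """Interior angles of the CA trace (radians), one per interior residue."""
    u = ca[:-2] - ca[1:-1]
    v = ca[2:] - ca[1:-1]
    nu = np.sqrt(np.einsum("ij,ij->i", u, u))
    nv = np.sqrt(np.einsum("ij,ij->i", v, v))
    c = np.einsum("ij,ij->i", u, v) / np.maximum(nu * nv, 1e-12)
    return np.arccos(np.clip(c, -1.0, 1.0))


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product of (n, 3) arrays (faster than np.cross)."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _dihedrals(ca: np.ndarray) -> np.ndarray:
    """Dihedral angles of the CA trace (radians, signed)."""
    b1 = ca[1:-2] - ca[:-3]
    b2 = ca[2:-1] - ca[1:-2]
    b3 = ca[3:] - ca[2:-1]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    b2n = np.sqrt(np.einsum("ij,ij->i", b2, b2))
    m1 = _cross(n1, b2 / np.maximum(b2n, 1e-12)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


class HairpinModel:
    """Coarse-grained hairpin model exposing the sampler protocol.

    The sampler protocol consists of the attributes/methods ``kb``,
    ``energy``, ``energy_components``, ``propose``, ``initial_state``,
    ``observe`` and ``default_moves_per_sweep``.
    """

    kb = R_KCAL
    units = "physical"

    def __init__(
        self,
        topology: Topology,
        params: CGParameters | None = None,
        move_weights: dict[str, float] | None = None,
    ) -> None:
        self.topology = topology
        self.params = params or CGParameters()
        self.move_weights = dict(move_weights or {"local": 0.4, "crankshaft": 0.3, "pivot": 0.3})
        total = sum(self.move_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"move weights must sum to 1, got {total}")
        self._move_names = sorted(self.move_weights)
        self._move_probs = np.array([self.move_weights[m] for m in self._move_names])
        self._move_cumprobs = np.cumsum(self._move_probs)
        self._move_cumprobs[-1] = 1.0
        self.n_residues = topology.n_residues

        # Precompute index arrays for vectorized energy evaluation.
        self._registry = np.array(topology.hbond_registry, dtype=int)
        self._sc_pairs = [
            (np.array(a, dtype=int), np.array(b, dtype=int))
            for a, b in topology.sidechain_pairs
        ]
        iu = np.triu_indices(self.n_residues, k=2)
        self._ev_i, self._ev_j = iu
        charges = np.array([_RESIDUE_CHARGE.get(c, 0.0) for c in topology.sequence])
        qq = charges[self._ev_i] * charges[self._ev_j]
        self._charged_mask = qq != 0.0
        self._qq = qq[self._charged_mask]

        # Native loop geometry targets: interior angles at the loop residues
        # and dihedrals fully inside the loop segment.
        native = native_ca_coordinates(self.n_residues)
        lo, hi = topology.loop_residues
        angle_res = np.arange(1, self.n_residues - 1)  # residues 2..n-1 (1-based)
        self._loop_angle_mask = (angle_res + 1 >= lo) & (angle_res + 1 <= hi)
        self._native_angles = _angles(native)
        dihe_first = np.arange(1, self.n_residues - 2)  # dihedral starts at residue i..i+3
        self._loop_dihe_mask = (dihe_first >= lo) & (dihe_first + 3 <= hi)
        self._native_dihedrals = _dihedrals(native)

    # -- energies --------------------------------------------------------
    def energy_components(self, ca: np.ndarray) -> dict[str, float]:
        p = self.params
        ca = np.asarray(ca, dtype=float)
        comps: dict[str, float] = {}

        # bonded
        dvec = np.diff(ca, axis=0)
        bonds = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        e_bond = p.bond_k * np.sum((bonds - p.bond_r0) ** 2)
        theta = _angles(ca)
        theta0 = math.radians(p.angle_theta0_deg)
        k_angle = np.where(
            self._loop_angle_mask, p.lambda_loop * p.loop_angle_k, p.angle_k
        )
        theta_ref = np.where(self._loop_angle_mask, self._native_angles, theta0)
        e_angle = np.sum(k_angle * (theta - theta_ref) ** 2)
        phi = _dihedrals(ca)
        dphi = phi - self._native_dihedrals
        # generic weak cosine dihedral outside the loop; harmonic-in-cosine
        # restraint to the native turn dihedrals inside it
        e_dihe = np.sum(
            np.where(
                self._loop_dihe_mask,
                p.lambda_loop * p.loop_dihedral_k * (1.0 - np.cos(dphi)),
                p.dihedral_k * (1.0 + np.cos(phi)),
            )
        )
        comps["bonded"] = float(e_bond + e_angle + e_dihe)

        # excluded volume (soft core; finite at d = 0)
        dv = ca[self._ev_i] - ca[self._ev_j]
        d2 = np.einsum("ij,ij->i", dv, dv)
        comps["excluded_volume"] = float(
            p.excluded_epsilon * np.sum((p.excluded_sigma**2 / (d2 + 0.25)) ** 6)
        )

        # native-contact wells need the surrogate beads
        coords = place_surrogate_beads(ca, self.topology)
        if p.eps_hb > 0.0 and len(self._registry):
            rv = coords[self._registry[:, 0]] - coords[self._registry[:, 1]]
            d = np.sqrt(np.einsum("ij,ij->i", rv, rv))
            comps["hbond_contact"] = float(-p.eps_hb * np.sum(_switch(d, p.hb_r_on, p.hb_r_off)))
        else:
            comps["hbond_contact"] = 0.0
        if p.eps_sc > 0.0 and self._sc_pairs:
            e_sc = 0.0
            for a, b in self._sc_pairs:
                dmin = np.min(
                    np.linalg.norm(coords[a][:, None, :] - coords[b][None, :, :], axis=-1)
                )
                e_sc -= p.eps_sc * _switch(np.array([dmin]), p.sc_r_on, p.sc_r_off)[0]
            comps["sidechain_contact"] = float(e_sc)
        else:
            comps["sidechain_contact"] = 0.0

        if p.charge_strength != 0.0 and self._qq.size:
            d = np.sqrt(d2[self._charged_mask] + 1.0)  # softened at contact
            comps["screened_charge"] = float(
                p.charge_strength * np.sum(self._qq * np.exp(-d / p.debye_length) / d)
            )
        else:
            comps["screened_charge"] = 0.0
        return comps

    def energy(self, ca: np.ndarray) -> float:
        return float(sum(self.energy_components(ca).values()))

    # -- moves -----------------------------------------------------------
    @property
    def default_moves_per_sweep(self) -> int:
        return self.n_residues

    def propose(self, ca: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Symmetric move proposal: local displacement, crankshaft or pivot."""
        u = rng.random()
        kind = self._move_names[int(np.searchsorted(self._move_cumprobs, u, side="right"))]
        return self.propose_move(ca, kind, rng)

    def propose_move(
        self, ca: np.ndarray, kind: str, rng: np.random.Generator, amplitude: float | None = None
    ) -> np.ndarray:
        new = np.array(ca, dtype=float, copy=True)
        n = self.n_residues
        if kind == "local":
            amp = 0.35 if amplitude is None else amplitude
            i = int(rng.integers(n))
            new[i] += rng.normal(0.0, amp, size=3)
        elif kind == "crankshaft":
            amp = 0.9 if amplitude is None else amplitude
            i = int(rng.integers(0, n - 2))
            j = int(rng.integers(i + 2, n))
            angle = rng.uniform(-amp, amp)
            new[i + 1 : j] = _rotate_about_axis(new[i + 1 : j], new[i], new[j] - new[i], angle)
        elif kind == "pivot":
            amp = 0.9 if amplitude is None else amplitude
            i = int(rng.integers(1, n - 1))
            axis = _random_unit(rng)
            angle = rng.uniform(-amp, amp)
            if rng.random() < 0.5:
                new[i + 1 :] = _rotate_about_axis(new[i + 1 :], new[i], axis, angle)
            else:
                new[:i] = _rotate_about_axis(new[:i], new[i], axis, angle)
        else:
            raise ValueError(f"unknown move kind {kind!r}")
        return new

    # -- sampler plumbing -------------------------------------------------
    def initial_state(self, rng: np.random.Generator) -> np.ndarray:
        """Fully extended chain with a small seeded jitter."""
        ca = extended_ca_coordinates(self.n_residues)
        return ca + rng.normal(0.0, 0.05, size=ca.shape)

    def observe(self, ca: np.ndarray) -> dict[str, float]:
        from . import metrics  # local import to avoid a cycle

        frame = self.make_frame(ca)
        comps = frame.energy_components
        return {
            "n_hb": float(metrics.count_native_hbonds(frame, self.topology)),
            "n_sc": float(metrics.count_sidechain_contacts(frame, self.topology)),
            "loop_distance": metrics.loop_distance(frame, self.topology),
            "end_to_end": metrics.end_to_end(frame, self.topology),
            **{f"e_{k}": v for k, v in comps.items()},
        }

    def make_frame(
        self, ca: np.ndarray, temperature: float = 0.0, replica_id: int = -1, step: int = -1
    ) -> Frame:
        comps = self.energy_components(ca)
        return Frame(
            coordinates=place_surrogate_beads(ca, self.topology),
            energy_components=comps,
            total_energy=float(sum(comps.values())),
            temperature=temperature,
            replica_id=replica_id,
            step=step,
        )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_about_axis(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle: float
) -> np.ndarray:
    """Rodrigues rotation of points about an axis through origin."""
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return points
    k = axis / norm
    p = points - origin
    cos, sin = math.cos(angle), math.sin(angle)
    rotated = p * cos + np.cross(k, p) * sin + np.outer(p @ k, k) * (1.0 - cos)
    return rotated + origin


def cg_energy(
    ca_coordinates: np.ndarray, topology: Topology, params: CGParameters | None = None
) -> tuple[dict[str, float], float]:
    """Energy components and total for one CA conformation.

    Convenience wrapper around :class:`HairpinModel` for one-off
    evaluations; deterministic in its inputs.
    """
    model = HairpinModel(topology, params)
    comps = model.energy_components(np.asarray(ca_coordinates, dtype=float))
    return comps, float(sum(comps.values()))


def build_native_fixture(
    topology: Topology, params: CGParameters | None = None
) -> Frame:
    """Idealized folded reference frame: all 7 registry H-bonds and both
    side-chain contacts satisfied."""
    model = HairpinModel(topology, params)
    return model.make_frame(native_ca_coordinates(topology.n_residues))


def build_extended_fixture(
    topology: Topology, params: CGParameters | None = None
) -> Frame:
    """Fully extended reference frame: no native contacts formed."""
    model = HairpinModel(topology, params)
    return model.make_frame(extended_ca_coordinates(topology.n_residues))
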