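"""Coarse-grained chain geometry: surrogate-bead placement and reference
conformations.

The chain's independent degrees of freedom are the CA bead positions.  The
O, HN and SC beads are *derived*: they are placed deterministically from the
local CA geometry, so any function of bead coordinates is automatically
covariant under rigid transformations of the CA trace.

Placement rule for residue ``i`` with neighbours ``i-1`` and ``i+1``:

* tangent ``t_i`` = unit vector from CA_{i-1} to CA_{i+1} (one-sided at the
  termini);
* bend normal ``n_i`` = unit vector from CA_i towards the midpoint of its
  neighbours (the local bisector).  For a locally straight chain the bend
  vector vanishes and the normal offset is dropped;
* ``O_i  = CA_i + C_NORMAL * n_i + C_TANGENT * t_i``
* ``HN_i = CA_i + C_NORMAL * n_i - C_TANGENT * t_i``
* ``SC_i = CA_i - C_SC * n_i`` (side chains sit on the face opposite the
  backbone polar groups, as in a pleated beta-strand).

The native reference geometry is an idealized two-stranded antiparallel
hairpin with a pleat of amplitude ``PLEAT`` about each strand axis; the
pleat phase is chosen so that the bend normals of the registry residues
point across the strand gap, which makes the surrogate O/HN beads of each
native pair approach within the 2.6 A hydrogen-bond criterion.
"""

from __future__ import annotations

import numpy as np

from .topology import Topology

__all__ = [
    "place_surrogate_beads",
    "build_bead_coordinates",
    "native_ca_coordinates",
    "extended_ca_coordinates",
]

# Surrogate-bead offsets (Angstrom).
C_NORMAL = 1.8
C_TANGENT = 0.8
C_SC = 1.0
_STRAIGHT_TOL = 1e-8

# Native-geometry constants (Angstrom).
BOND_LENGTH = 3.8          # consecutive CA-CA distance
PLEAT = 0.6                # in-plane zigzag amplitude of each strand
STRAND_GAP = 4.2           # distance between the two strand axes
_RISE = float(np.sqrt(BOND_LENGTH**2 - (2 * PLEAT) ** 2))  # per-residue rise


def _local_frames(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue unit tangents and bend normals of a CA trace.

    Returns (t, n) with shape (n_res, 3) each.  The bend normal is zero for
    terminal residues and wherever the chain is locally straight.
    """
    n_res = ca.shape[0]
    t = np.zeros_like(ca)
    m = np.zeros_like(ca)
    if n_res >= 2:
        t[0] = ca[1] - ca[0]
        t[-1] = ca[-1] - ca[-2]
    if n_res >= 3:
        t[1:-1] = ca[2:] - ca[:-2]
        m[1:-1] = 0.5 * (ca[2:] + ca[:-2]) - ca[1:-1]
    t_norm = np.sqrt(np.einsum("ij,ij->i", t, t))[:, None]
    t = np.where(t_norm > _STRAIGHT_TOL, t / np.maximum(t_norm, _STRAIGHT_TOL), 0.0)
    m_norm = np.sqrt(np.einsum("ij,ij->i", m, m))[:, None]
    n = np.where(m_norm > _STRAIGHT_TOL, m / np.maximum(m_norm, _STRAIGHT_TOL), 0.0)
    return t, n


# Per-topology cache of (bead indices, residue indices) per role, keyed by
# object identity (topologies are built once and reused).
_ROLE_INDEX_CACHE: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}


def _role_indices(topology: Topology) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    cached = _ROLE_INDEX_CACHE.get(id(topology))
    if cached is not None:
        return cached
    table: dict[str, tuple[list[int], list[int]]] = {}
    for i, bead in enumerate(topology.beads):
        table.setdefault(bead.role, ([], []))
        table[bead.role][0].append(i)
        table[bead.role][1].append(bead.residue - 1)
    out = {
        role: (np.array(idx, dtype=int), np.array(res, dtype=int))
        for role, (idx, res) in table.items()
    }
    _ROLE_INDEX_CACHE[id(topology)] = out
    return out


def place_surrogate_beads(ca: np.ndarray, topology: Topology) -> np.ndarray:
    """Full bead coordinate array from the CA trace.

    Parameters
    ----------
    ca : (n_residues, 3) array of CA positions.
    topology : the bead layout to fill.

    Returns
    -------
    (topology.n_beads, 3) array with CA beads copied through and O/HN/SC
    beads placed by the local-frame rule.
    """
    ca = np.asarray(ca, dtype=float)
    if ca.shape != (topology.n_residues, 3):
        raise ValueError(
            f"expected CA array of shape ({topology.n_residues}, 3), got {ca.shape}"
        )
    t, n = _local_frames(ca)
    roles = _role_indices(topology)
    coords = np.empty((topology.n_beads, 3), dtype=float)
    idx, res = roles["CA"]
    coords[idx] = ca[res]
    if "O" in roles:
        idx, res = roles["O"]
        coords[idx] = ca[res] + C_NORMAL * n[res] + C_TANGENT * t[res]
    if "HN" in roles:
        idx, res = roles["HN"]
        coords[idx] = ca[res] + C_NORMAL * n[res] - C_TANGENT * t[res]
    if "SC" in roles:
        idx, res = roles["SC"]
        coords[idx] = ca[res] - C_SC * n[res]
    return coords


# Kept as an alias: "build the full bead set from the CA trace".
build_bead_coordinates = place_surrogate_beads


def native_ca_coordinates(n_residues: int = 16) -> np.ndarray:
    """Idealized folded-hairpin CA trace.

    Strand 1 (residues 1-7) runs along +y at x ~ 0, strand 2 (residues
    10-16) runs along -y at x ~ STRAND_GAP, and residues 8-9 form a
    chain-crossing turn.  The pleat phase puts the bend normals of registry
    residues (2, 4, 6, 7 and 10, 11, 13, 15) across the strand gap.
    """
    if n_residues != 16:
        raise ValueError("the packaged native geometry is defined for 16 residues")
    ca = np.zeros((16, 3))
    w = STRAND_GAP
    # Strand 1: even residues bulge away from strand 2 (x = -PLEAT) so their
    # bend normals point towards it.
    for i in range(1, 8):  # residues 1..7
        x = PLEAT if i % 2 == 1 else -PLEAT
        ca[i - 1] = (x, (i - 1) * _RISE, 0.0)
    # Strand 2: residue j pairs with residue 17 - j at the same height.
    for j in range(10, 17):  # residues 10..16
        x = w + PLEAT if j % 2 == 1 else w - PLEAT
        ca[j - 1] = (x, (16 - j) * _RISE, 0.0)
    # Chain-crossing turn: residue 8 overshoots in x, residue 9 comes back,
    # so the bend normals of residues 7 and 10 point across the gap.
    y_top = 6 * _RISE
    ca[7] = (w / 2 + 1.5, y_top + 2.6, 0.9)   # residue 8
    ca[8] = (w / 2 - 1.5, y_top + 2.6, -0.9)  # residue 9
    return ca


def extended_ca_coordinates(n_residues: int = 16) -> np.ndarray:
    """Fully extended CA trace along +y (locally straight chain)."""
    ca = np.zeros((n_residues, 3))
    ca[:, 1] = BOND_LENGTH * np.arange(n_residues)
    return ca
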