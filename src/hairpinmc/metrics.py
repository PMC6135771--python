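"""Per-frame structural observables.

All criteria are inclusive distance cut-offs on bead coordinates:

* a native backbone H-bond counts when the registry donor HN bead and
  acceptor O bead are within ``HBOND_CUTOFF`` (2.6 A);
* helicity is the mean frequency of i -> i+4 backbone H-bonds, using the
  same 2.6 A criterion on d(O_i, HN_{i+4});
* a native side-chain contact counts when the minimum distance between the
  two side-chain bead groups is within the side-chain cut-off.  For
  all-atom inputs with full heavy-atom side chains the conventional
  criterion is 4.2 A; the packaged coarse-grained hairpins represent each
  contact side chain by a single bead and use a wider default
  (``SIDECHAIN_CUTOFF_CG``, 6.5 A);
* the loop distance is the CA-CA distance of the loop residues (6 and 11)
  and the end-to-end distance that of the termini.

Counts depend on coordinates only through interbead distances, so all
observables are invariant under rigid transformations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frame import Frame
from .topology import Topology

__all__ = [
    "HBOND_CUTOFF",
    "SIDECHAIN_CUTOFF_CG",
    "SIDECHAIN_CUTOFF_ALLATOM",
    "count_native_hbonds",
    "count_sidechain_contacts",
    "helicity",
    "loop_distance",
    "end_to_end",
    "observable_table",
]

HBOND_CUTOFF = 2.6
SIDECHAIN_CUTOFF_CG = 6.5
SIDECHAIN_CUTOFF_ALLATOM = 4.2


def _coords(frame: Frame | np.ndarray) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.coordinates
    return np.asarray(frame, dtype=float)


def count_native_hbonds(
    frame: Frame | np.ndarray, topology: Topology, cutoff: float = HBOND_CUTOFF
) -> int:
    """Number of native-registry H-bond pairs with donor-acceptor distance
    no greater than ``cutoff``."""
    coords = _coords(frame)
    n = 0
    for hn, o in topology.hbond_registry:
        if hn >= coords.shape[0] or o >= coords.shape[0]:
            raise ValueError(
                f"registry pair (HN bead {hn}, O bead {o}) missing from frame with "
                f"{coords.shape[0]} beads"
            )
        if np.linalg.norm(coords[hn] - coords[o]) <= cutoff:
            n += 1
    return n


def count_sidechain_contacts(
    frame: Frame | np.ndarray, topology: Topology, cutoff: float = SIDECHAIN_CUTOFF_CG
) -> int:
    """Number of native side-chain pairs whose minimum inter-group bead
    distance is no greater than ``cutoff``."""
    coords = _coords(frame)
    n = 0
    for left, right in topology.sidechain_pairs:
        if len(left) == 0 or len(right) == 0:
            raise ValueError("empty side-chain contact group")
        a = coords[np.asarray(left, dtype=int)]
        b = coords[np.asarray(right, dtype=int)]
        dmin = np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1))
        if dmin <= cutoff:
            n += 1
    return n


def helicity(
    frames, topology: Topology, cutoff: float = HBOND_CUTOFF
) -> float:
    """Mean i -> i+4 backbone H-bond frequency over frames and eligible pairs.

    A pair (i, i+4) is eligible when both the O bead of residue ``i`` and the
    HN bead of residue ``i + 4`` exist in the topology.
    """
    pairs = [
        (topology.bead_index(i, "O"), topology.bead_index(i + 4, "HN"))
        for i in range(1, topology.n_residues - 3)
        if topology.has_bead(i, "O") and topology.has_bead(i + 4, "HN")
    ]
    if not pairs:
        raise ValueError(
            f"topology {topology.name!r} has no eligible (O_i, HN_i+4) pairs"
        )
    frames = list(frames)
    if not frames:
        raise ValueError("helicity needs at least one frame")
    total = 0
    for frame in frames:
        coords = _coords(frame)
        for o, hn in pairs:
            if np.linalg.norm(coords[o] - coords[hn]) <= cutoff:
                total += 1
    return total / (len(frames) * len(pairs))


def _ca_distance(frame: Frame | np.ndarray, topology: Topology, residues) -> float:
    coords = _coords(frame)
    i = topology.bead_index(residues[0], "CA")
    j = topology.bead_index(residues[1], "CA")
    return float(np.linalg.norm(coords[i] - coords[j]))


def loop_distance(frame: Frame | np.ndarray, topology: Topology) -> float:
    """CA-CA distance across the loop (residues 6 and 11 for hairpins)."""
    return _ca_distance(frame, topology, topology.loop_residues)


def end_to_end(frame: Frame | np.ndarray, topology: Topology) -> float:
    """CA-CA distance between the chain termini."""
    return _ca_distance(frame, topology, topology.termini_residues)


def observable_table(
    frames,
    topology: Topology,
    hbond_cutoff: float = HBOND_CUTOFF,
    sidechain_cutoff: float = SIDECHAIN_CUTOFF_CG,
) -> pd.DataFrame:
    """Per-frame observable rows for a list of frames.

    One row per frame (none dropped): step, temperature, replica_id, n_hb,
    n_sc, loop_distance, end_to_end, total energy and the energy components.
    """
    rows = []
    for frame in frames:
        row = {
            "step": frame.step,
            "temperature": frame.temperature,
            "replica_id": frame.replica_id,
            "n_hb": count_native_hbonds(frame, topology, hbond_cutoff),
            "n_sc": count_sidechain_contacts(frame, topology, sidechain_cutoff),
            "loop_distance": loop_distance(frame, topology),
            "end_to_end": end_to_end(frame, topology),
            "total_energy": frame.total_energy,
        }
        for name, value in frame.energy_components.items():
            row[f"e_{name}"] = value
        rows.append(row)
    if not rows:
        raise ValueError("observable_table needs at least one frame")
    return pd.DataFrame(rows)
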