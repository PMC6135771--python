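"""Bead-level topologies for the GB1p-series beta-hairpins.

A hairpin is described at four beads per residue at most:

* ``CA``  — the backbone alpha-carbon bead; the only independent degree of
  freedom of the coarse-grained chain.
* ``O`` / ``HN`` — carbonyl-oxygen and amide-hydrogen surrogate beads used by
  the hydrogen-bond distance criterion.  They are placed deterministically
  off the local backbone (see :func:`place_surrogate_beads`).
* ``SC`` — a single side-chain bead for the residues participating in the
  native cross-strand hydrophobic contacts.

The native hydrogen-bond registry of the protein G B1 C-terminal hairpin
comprises seven donor/acceptor pairs; in literature numbering (residues
41-56) they are 42NH-55CO, 42CO-55NH, 44NH-53CO, 44CO-53NH, 46NH-51CO,
46CO-51NH and 47CO-50NH.  Topologies use local 1-based numbering, residue 41
mapping to 1, so the registry lives on residue pairs (2,15), (4,13), (6,11)
and (7,10).  The two native side-chain contacts (Trp43-Val54 and
Tyr45-Phe52 in the wild-type sequence) map to residue pairs (3,14) and
(5,12); the HP5A and GB1m3 variants keep the same positions with substituted
side chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bead",
    "Topology",
    "HAIRPIN_SEQUENCES",
    "LITERATURE_NUMBERING_OFFSET",
    "build_hairpin_topology",
]

#: One-letter sequences of the three hairpins (local residues 1-16).
HAIRPIN_SEQUENCES: dict[str, str] = {
    "GB1p": "GEWTYDDATKTFTVTE",
    "HP5A": "KKYTWNPATGKATVQE",
    "GB1m3": "KKWTYNPATGKFTVQE",
}

#: literature residue number = local number + offset (41 -> 1).
LITERATURE_NUMBERING_OFFSET: int = 40

# Native backbone H-bond registry as (donor residue, acceptor residue) in
# local numbering; donor contributes its HN bead, acceptor its O bead.
_HBOND_REGISTRY_RESIDUES: tuple[tuple[int, int], ...] = (
    (2, 15),   # 42NH-55CO
    (15, 2),   # 42CO-55NH
    (4, 13),   # 44NH-53CO
    (13, 4),   # 44CO-53NH
    (6, 11),   # 46NH-51CO
    (11, 6),   # 46CO-51NH
    (10, 7),   # 47CO-50NH
)

_SIDECHAIN_PAIR_RESIDUES: tuple[tuple[int, int], ...] = ((3, 14), (5, 12))

_LOOP_RESIDUES: tuple[int, int] = (6, 11)
_TERMINI_RESIDUES: tuple[int, int] = (1, 16)


@dataclass(frozen=True)
class Bead:
    """A single bead: 1-based residue index and role (CA, O, HN or SC)."""

    residue: int
    role: str


@dataclass
class Topology:
    """Bead-level description of a peptide chain.

    ``hbond_registry`` holds (HN bead index, O bead index) pairs and
    ``sidechain_pairs`` holds pairs of tuples of SC bead indices (a side
    chain may in general comprise several beads; the packaged hairpins use
    one bead per contact side chain).
    """

    name: str
    sequence: str
    beads: list[Bead]
    hbond_registry: list[tuple[int, int]]
    sidechain_pairs: list[tuple[tuple[int, ...], tuple[int, ...]]]
    loop_residues: tuple[int, int] = _LOOP_RESIDUES
    termini_residues: tuple[int, int] = _TERMINI_RESIDUES
    numbering_offset: int = LITERATURE_NUMBERING_OFFSET
    _index: dict[tuple[int, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {(b.residue, b.role): i for i, b in enumerate(self.beads)}
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def bead_index(self, residue: int, role: str) -> int:
        """Index of the bead with the given residue and role.

        Raises ``KeyError`` with an explicit message when absent.
        """
        try:
            return self._index[(residue, role)]
        except KeyError:
            raise KeyError(
                f"topology {self.name!r} has no bead (residue={residue}, role={role!r})"
            ) from None

    def has_bead(self, residue: int, role: str) -> bool:
        return (residue, role) in self._index

    @property
    def ca_indices(self) -> np.ndarray:
        """Bead indices of the CA beads, in residue order."""
        return np.array(
            [self.bead_index(r, "CA") for r in range(1, self.n_residues + 1)], dtype=int
        )

    def to_literature_residue(self, local: int) -> int:
        return local + self.numbering_offset

    def from_literature_residue(self, literature: int) -> int:
        return literature - self.numbering_offset

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n = self.n_beads
        for hn, o in self.hbond_registry:
            if not (0 <= hn < n and 0 <= o < n):
                raise ValueError(
                    f"H-bond registry entry ({hn}, {o}) references a bead outside "
                    f"the topology (n_beads={n})"
                )
            if self.beads[hn].role != "HN" or self.beads[o].role != "O":
                raise ValueError(
                    f"H-bond registry entry ({hn}, {o}) must pair an HN bead with an O bead"
                )
        for left, right in self.sidechain_pairs:
            for group in (left, right):
                if len(group) == 0:
                    raise ValueError("side-chain contact group is empty")
                for idx in group:
                    if not 0 <= idx < n:
                        raise ValueError(
                            f"side-chain group bead {idx} outside topology (n_beads={n})"
                        )
        for residue in (*self.loop_residues, *self.termini_residues):
            self.bead_index(residue, "CA")


def build_hairpin_topology(sequence_name: str) -> Topology:
    """Build the bead topology for one of the packaged hairpins.

    Parameters
    ----------
    sequence_name : str
        One of ``"GB1p"``, ``"HP5A"`` or ``"GB1m3"``.

    Returns
    -------
    Topology
        16 residues, each with CA, O and HN beads; SC beads on the four
        contact residues; the 7-entry native H-bond registry and the two
        native side-chain contact pairs.
    """
    if sequence_name not in HAIRPIN_SEQUENCES:
        valid = ", ".join(sorted(HAIRPIN_SEQUENCES))
        raise ValueError(
            f"unknown hairpin {sequence_name!r}; valid names are: {valid}"
        )
    sequence = HAIRPIN_SEQUENCES[sequence_name]
    sc_residues = sorted({r for pair in _SIDECHAIN_PAIR_RESIDUES for r in pair})

    beads: list[Bead] = []
    for residue in range(1, len(sequence) + 1):
        beads.append(Bead(residue, "CA"))
        beads.append(Bead(residue, "O"))
        beads.append(Bead(residue, "HN"))
        if residue in sc_residues:
            beads.append(Bead(residue, "SC"))

    index = {(b.residue, b.role): i for i, b in enumerate(beads)}
    registry = [
        (index[(donor, "HN")], index[(acceptor, "O")])
        for donor, acceptor in _HBOND_REGISTRY_RESIDUES
    ]
    sc_pairs = [
        ((index[(a, "SC")],), (index[(b, "SC")],))
        for a, b in _SIDECHAIN_PAIR_RESIDUES
    ]
    return Topology(
        name=sequence_name,
        sequence=sequence,
        beads=beads,
        hbond_registry=registry,
        sidechain_pairs=sc_pairs,
    )
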