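"""The Frame container: one conformation plus its energies and provenance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Frame"]


@dataclass
class Frame:
    """A single sampled conformation.

    Attributes
    ----------
    coordinates : (n_beads, 3) float array, Angstrom.
    energy_components : mapping term name -> energy (kcal/mol or reduced).
    total_energy : sum of the components.
    temperature : temperature at which the frame was sampled.
    replica_id : replica that generated the frame (-1 when not applicable).
    step : sweep/step index (-1 when not applicable).
    """

    coordinates: np.ndarray
    energy_components: dict[str, float] = field(default_factory=dict)
    total_energy: float = 0.0
    temperature: float = 0.0
    replica_id: int = -1
    step: int = -1

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_beads, 3) array")
        if self.energy_components:
            total = float(sum(self.energy_components.values()))
            if not np.isclose(total, self.total_energy, rtol=0.0, atol=1e-9 * max(1.0, abs(total))):
                raise ValueError(
                    f"total_energy {self.total_energy} does not equal the sum of "
                    f"energy_components {total}"
                )
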