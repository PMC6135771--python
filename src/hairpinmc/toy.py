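"""Harmonic test potentials used to validate the samplers.

For a 1D harmonic potential U(x) = k x^2 / 2 at temperature T the canonical
averages are exact: <x> = 0, <x^2> = kb T / k, <U> = kb T / 2.  These closed
forms back the sampler-validation tests.
"""

from __future__ import annotations

import numpy as np

from .constants import KB_REDUCED

__all__ = ["HarmonicModel"]


class HarmonicModel:
    """1D harmonic oscillator exposing the sampler protocol."""

    def __init__(self, k: float = 1.0, step_amplitude: float = 1.0, kb: float = KB_REDUCED):
        if k <= 0:
            raise ValueError("force constant must be positive")
        self.k = k
        self.step_amplitude = step_amplitude
        self.kb = kb
        self.units = "reduced" if kb == KB_REDUCED else "physical"

    @property
    def default_moves_per_sweep(self) -> int:
        return 1

    def energy(self, x: float) -> float:
        return 0.5 * self.k * float(x) ** 2

    def propose(self, x: float, rng: np.random.Generator) -> float:
        return float(x) + rng.normal(0.0, self.step_amplitude)

    def initial_state(self, rng: np.random.Generator) -> float:
        return float(rng.normal(0.0, 1.0))

    def observe(self, x: float) -> dict[str, float]:
        return {"x": float(x), "x2": float(x) ** 2}
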