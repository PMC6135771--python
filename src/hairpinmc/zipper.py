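"""Exactly solvable zipper model of hairpin hydrogen-bond formation.

The model's microstate is the number ``N`` of native backbone H-bonds
formed, ``0 <= N <= n_bonds`` (7 for the packaged hairpins).  A state with
``N`` bonds has energy ``E(N) = -N * epsilon`` and degeneracy ``Omega(N)``,
so the partition function is

    Z(T) = sum_N Omega(N) * exp(N * epsilon / (kb * T)).

``Omega`` encodes the conformational (chiefly loop) entropy: a flexible
loop corresponds to large degeneracies at low ``N``.  Because every
thermodynamic quantity follows from a 8-term sum, the model serves as the
analytic oracle for the sampling and analysis machinery: the same
folded/unfolded classification thresholds used on simulation data
(``N >= 4`` folded, ``N <= 1`` unfolded) are applied to the exact
populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import KB_REDUCED

__all__ = [
    "ZipperModel",
    "ZipperThermo",
    "zipper_exact",
    "zipper_tm",
    "zipper_mc_step",
    "ZipperSampler",
    "two_level_model",
]

FOLDED_THRESHOLD = 4
UNFOLDED_THRESHOLD = 1


@dataclass
class ZipperModel:
    """Discrete zipper model: ``n_bonds``, per-bond energy ``epsilon`` and
    degeneracy vector ``degeneracy`` of length ``n_bonds + 1``."""

    n_bonds: int
    epsilon: float
    degeneracy: np.ndarray
    kb: float = KB_REDUCED

    def __post_init__(self) -> None:
        self.degeneracy = np.asarray(self.degeneracy, dtype=float)
        if self.degeneracy.shape != (self.n_bonds + 1,):
            raise ValueError(
                f"degeneracy must have length n_bonds + 1 = {self.n_bonds + 1}"
            )
        if np.any(self.degeneracy < 0):
            raise ValueError("degeneracies must be non-negative")
        if self.degeneracy[self.n_bonds] < 1:
            raise ValueError("the fully zipped state must have degeneracy >= 1")
        if np.count_nonzero(self.degeneracy) < 2:
            raise ValueError("at least two states must have nonzero degeneracy")

    def state_energy(self, n: int | np.ndarray) -> np.ndarray | float:
        return -np.asarray(n, dtype=float) * self.epsilon

    @property
    def support(self) -> np.ndarray:
        """Sorted state indices with nonzero degeneracy."""
        return np.flatnonzero(self.degeneracy > 0)


@dataclass
class ZipperThermo:
    """Exact thermodynamics of a zipper model at one temperature."""

    temperature: float
    partition_function: float
    populations: np.ndarray
    pf: float
    pu: float
    delta_g: float
    delta_u: float
    delta_s: float


def zipper_exact(
    model: ZipperModel,
    temperature: float,
    folded_threshold: int = FOLDED_THRESHOLD,
    unfolded_threshold: int = UNFOLDED_THRESHOLD,
) -> ZipperThermo:
    """Exact populations and folding thermodynamics by state enumeration.

    ``delta_g = -kb T ln(Pf/Pu)``, ``delta_u`` is the difference of the
    folded and unfolded sub-ensemble mean energies and ``delta_s`` follows
    from the identity ``(delta_u - delta_g) / T``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / (model.kb * temperature)
    n = np.arange(model.n_bonds + 1)
    energies = model.state_energy(n)
    # log-sum-exp for numerical stability at low temperature
    log_w = np.where(
        model.degeneracy > 0, np.log(np.maximum(model.degeneracy, 1e-300)) - beta * energies, -np.inf
    )
    log_z = float(np.logaddexp.reduce(log_w))
    populations = np.exp(log_w - log_z)
    pf = float(populations[n >= folded_threshold].sum())
    pu = float(populations[n <= unfolded_threshold].sum())
    if pf <= 0 or pu <= 0:
        raise ValueError(
            "folded or unfolded population is exactly zero; the model cannot "
            "be analyzed with these thresholds"
        )
    delta_g = -model.kb * temperature * float(np.log(pf / pu))
    u_f = float((populations * energies)[n >= folded_threshold].sum()) / pf
    u_u = float((populations * energies)[n <= unfolded_threshold].sum()) / pu
    delta_u = u_f - u_u
    delta_s = (delta_u - delta_g) / temperature
    return ZipperThermo(
        temperature=temperature,
        partition_function=float(np.exp(log_z)),
        populations=populations,
        pf=pf,
        pu=pu,
        delta_g=delta_g,
        delta_u=delta_u,
        delta_s=delta_s,
    )


def zipper_tm(model: ZipperModel, t_lo: float = 1e-3, t_hi: float = 1e3) -> float:
    """Exact melting temperature: the root of delta_g(T) = 0."""
    f = lambda t: zipper_exact(model, t).delta_g
    return float(brentq(f, t_lo, t_hi))


def zipper_mc_step(
    state: int, model: ZipperModel, temperature: float, rng: np.random.Generator
) -> int:
    """One Metropolis step on the zipper state.

    The proposal steps to the adjacent state *within the support* of the
    degeneracy vector (states with ``Omega = 0`` carry zero weight and are
    skipped), reflecting at the ends by proposal rejection.  Acceptance is
    Metropolis on the free-energy weight ``Omega(N) exp(-beta E(N))``, so
    the chain's stationary distribution is the exact Boltzmann distribution
    over the support.
    """
    support = model.support
    pos = int(np.searchsorted(support, state))
    if pos >= len(support) or support[pos] != state:
        raise ValueError(f"state {state} is outside the model support")
    step = 1 if rng.random() < 0.5 else -1
    new_pos = pos + step
    if new_pos < 0 or new_pos >= len(support):
        return state  # reflect by rejection
    new = int(support[new_pos])
    beta = 1.0 / (model.kb * temperature)
    log_ratio = (
        np.log(model.degeneracy[new]) - np.log(model.degeneracy[state])
        - beta * (model.state_energy(new) - model.state_energy(state))
    )
    if log_ratio >= 0 or rng.random() < np.exp(log_ratio):
        return new
    return state


class ZipperSampler:
    """Sampler-protocol adapter around a :class:`ZipperModel`."""

    def __init__(self, model: ZipperModel) -> None:
        self.model = model
        self.kb = model.kb
        self.units = "reduced" if model.kb == KB_REDUCED else "physical"

    @property
    def default_moves_per_sweep(self) -> int:
        return 1

    def energy(self, state: int) -> float:
        return float(self.model.state_energy(state))

    def propose(self, state: int, rng: np.random.Generator) -> int:
        # Proposal only; Metropolis acceptance is applied by the sampler.
        # Degeneracy enters the acceptance through ``log_weight_correction``.
        support = self.model.support
        pos = int(np.searchsorted(support, state))
        step = 1 if rng.random() < 0.5 else -1
        new_pos = pos + step
        if new_pos < 0 or new_pos >= len(support):
            return state
        return int(support[new_pos])

    def log_weight_correction(self, state: int) -> float:
        """log Omega(N): the entropic part of the state weight."""
        return float(np.log(self.model.degeneracy[state]))

    def initial_state(self, rng: np.random.Generator) -> int:
        support = self.model.support
        return int(support[rng.integers(len(support))])

    def observe(self, state: int) -> dict[str, float]:
        return {
            "n_hb": float(state),
            "e_contact": float(self.model.state_energy(state)),
        }


def two_level_model(e0: float = 1.0, log_g: float = 2.0, n_bonds: int = 7) -> ZipperModel:
    """Two-level zipper: unfolded degeneracy ``g = exp(log_g)`` at N = 0 and
    a single folded state at N = n_bonds with energy ``-e0``.

    Closed form: Tm = e0 / (kb * log_g).
    """
    degeneracy = np.zeros(n_bonds + 1)
    degeneracy[0] = np.exp(log_g)
    degeneracy[n_bonds] = 1.0
    return ZipperModel(n_bonds=n_bonds, epsilon=e0 / n_bonds, degeneracy=degeneracy)
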