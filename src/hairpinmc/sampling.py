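"""Metropolis Monte Carlo and the replica-exchange (REX) engine.

A *sampler model* is any object exposing

* ``kb`` — Boltzmann constant in the model's units;
* ``energy(state) -> float``;
* ``propose(state, rng) -> new_state`` — a symmetric proposal;
* ``initial_state(rng) -> state``;
* ``observe(state) -> dict`` — scalar per-frame observables;
* ``default_moves_per_sweep`` — moves composing one sweep;
* optionally ``log_weight_correction(state)`` — an extra additive log-weight
  (e.g. a state degeneracy) entering the acceptance ratio.

REX protocol: each replica runs ``exchange_interval`` sweeps of plain
Metropolis at its current temperature between exchange attempts; attempts
alternate between even-indexed and odd-indexed neighbouring temperature
pairs so that all disjoint pairs are tried on alternating attempts, and a
pair swaps temperatures with probability
``min(1, exp[(beta_i - beta_j)(U_i - U_j)])``.  Randomness is split into one
independent stream per replica plus one stream for exchange decisions, all
spawned from the master seed, so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureLadder",
    "build_ladder",
    "metropolis_accept",
    "exchange_probability",
    "RunConfig",
    "RexRecord",
    "RexResult",
    "run_rex",
    "run_mc",
]


@dataclass
class TemperatureLadder:
    """A non-decreasing schedule of replica temperatures."""

    temperatures: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        # build_ladder enforces >= 2; a single temperature is permitted here
        # so that run_rex degenerates gracefully to plain MC.
        if self.temperatures.ndim != 1 or self.temperatures.size < 1:
            raise ValueError("a temperature ladder needs at least one temperature")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive")
        if np.any(np.diff(self.temperatures) < 0):
            raise ValueError("temperatures must be non-decreasing")

    @property
    def n_replicas(self) -> int:
        return int(self.temperatures.size)

    def __len__(self) -> int:
        return self.n_replicas


def build_ladder(t_min: float, t_max: float, n: int) -> TemperatureLadder:
    """Exponentially spaced ladder ``T_k = T_min (T_max/T_min)^(k/(n-1))``.

    Endpoints are exact; a degenerate range yields ``n`` copies of
    ``t_min``.
    """
    if n < 2:
        raise ValueError("a replica ladder needs n >= 2")
    if t_min <= 0:
        raise ValueError("t_min must be positive")
    if t_max < t_min:
        raise ValueError("t_max must be >= t_min")
    k = np.arange(n, dtype=float)
    temps = t_min * (t_max / t_min) ** (k / (n - 1))
    temps[0] = t_min
    temps[-1] = t_max
    return TemperatureLadder(temps)


def metropolis_accept(
    delta_e: float, temperature: float, rng: np.random.Generator, kb: float = 1.0
) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/kbT)).

    One uniform variate is always consumed, keeping the random stream's
    advance independent of the decision path.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    log_p = min(0.0, -delta_e / (kb * temperature))
    return rng.random() < math.exp(log_p)


def exchange_probability(beta_i: float, beta_j: float, u_i: float, u_j: float) -> float:
    """Replica-exchange acceptance probability
    ``min(1, exp[(beta_i - beta_j)(u_i - u_j)])``; symmetric in the pair."""
    if beta_i <= 0 or beta_j <= 0:
        raise ValueError("inverse temperatures must be positive")
    arg = (beta_i - beta_j) * (u_i - u_j)
    return float(min(1.0, math.exp(min(arg, 0.0))) if arg < 0 else 1.0)


@dataclass
class RunConfig:
    """Run-length and bookkeeping parameters for a REX run."""

    n_sweeps: int
    exchange_interval: int = 2
    production_fraction: float = 0.6
    seed: int = 0
    moves_per_sweep: int | None = None
    state_interval: int = 0  # 0: do not retain state snapshots

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1")
        if not 0 < self.production_fraction <= 1:
            raise ValueError("production_fraction must be in (0, 1]")
        if self.moves_per_sweep is not None and self.moves_per_sweep < 1:
            raise ValueError("moves_per_sweep must be >= 1")

    @property
    def production_start(self) -> int:
        """First sweep index inside the production window."""
        return int(math.floor(self.n_sweeps * (1.0 - self.production_fraction)))


@dataclass
class RexRecord:
    """Exchange bookkeeping of one REX run."""

    temperatures: np.ndarray
    temp_index_by_sweep: np.ndarray      # (n_sweeps, n_replicas) int
    attempt_sweep: np.ndarray            # (n_attempts,) int
    attempt_pair: np.ndarray             # (n_attempts,) int, lower temp index
    attempt_delta: np.ndarray            # (n_attempts,) float, log acceptance argument
    attempt_accepted: np.ndarray         # (n_attempts,) bool
    round_trips: np.ndarray              # (n_replicas,) int

    @property
    def n_replicas(self) -> int:
        return int(self.temperatures.size)

    def pair_acceptance(self) -> pd.DataFrame:
        """Per-neighbour-pair attempt counts and acceptance rates."""
        rows = []
        for pair in range(self.n_replicas - 1):
            mask = self.attempt_pair == pair
            n_att = int(mask.sum())
            n_acc = int(self.attempt_accepted[mask].sum())
            rows.append(
                {
                    "pair": pair,
                    "t_low": self.temperatures[pair],
                    "t_high": self.temperatures[pair + 1],
                    "attempts": n_att,
                    "accepted": n_acc,
                    "acceptance": n_acc / n_att if n_att else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RexRecord):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, name), getattr(other, name))
            for name in (
                "temperatures",
                "temp_index_by_sweep",
                "attempt_sweep",
                "attempt_pair",
                "attempt_delta",
                "attempt_accepted",
                "round_trips",
            )
        )


@dataclass
class RexResult:
    """Observables, exchange record and (optionally) state snapshots."""

    record: RexRecord
    observables: pd.DataFrame
    final_states: list
    state_snapshots: list = field(default_factory=list)  # (sweep, temp_index, state)
    config: RunConfig | None = None

    def stream(self, temp_index: int, production_only: bool = False) -> pd.DataFrame:
        """Demultiplexed per-temperature observable stream."""
        df = self.observables[self.observables["temp_index"] == temp_index]
        if production_only and self.config is not None:
            df = df[df["sweep"] >= self.config.production_start]
        return df.sort_values("sweep").reset_index(drop=True)

    def states_at(self, temp_index: int, production_only: bool = False):
        """State snapshots recorded at one temperature."""
        start = self.config.production_start if (production_only and self.config) else 0
        return [
            s for (sweep, t, s) in self.state_snapshots
            if t == temp_index and sweep >= start
        ]


def run_rex(model: Any, ladder: TemperatureLadder, config: RunConfig) -> RexResult:
    """Run replica-exchange Monte Carlo.

    Returns per-sweep observables for every replica (with both the replica
    id and its current temperature, enabling demultiplexing into
    per-temperature streams), the full exchange record, and optional state
    snapshots every ``config.state_interval`` sweeps.
    """
    temps = ladder.temperatures
    n_rep = ladder.n_replicas
    betas = 1.0 / (model.kb * temps)
    moves = config.moves_per_sweep or model.default_moves_per_sweep
    has_lwc = hasattr(model, "log_weight_correction")

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_rep + 1)
    rngs = [np.random.default_rng(c) for c in children[:n_rep]]
    rng_ex = np.random.default_rng(children[n_rep])

    states = [model.initial_state(rngs[r]) for r in range(n_rep)]
    energies = np.array([model.energy(s) for s in states], dtype=float)
    lwcs = np.array(
        [model.log_weight_correction(s) if has_lwc else 0.0 for s in states]
    )
    temp_of_replica = np.arange(n_rep)
    replica_at_temp = np.arange(n_rep)

    # observable storage (fixed schema from the first observation)
    first_obs = model.observe(states[0])
    obs_keys = list(first_obs)
    n_rows = config.n_sweeps * n_rep
    cols = {
        "sweep": np.empty(n_rows, dtype=np.int64),
        "replica_id": np.empty(n_rows, dtype=np.int64),
        "temp_index": np.empty(n_rows, dtype=np.int64),
        "temperature": np.empty(n_rows, dtype=float),
        "energy": np.empty(n_rows, dtype=float),
    }
    for key in obs_keys:
        cols[key] = np.empty(n_rows, dtype=float)

    temp_index_by_sweep = np.empty((config.n_sweeps, n_rep), dtype=np.int64)
    att_sweep: list[int] = []
    att_pair: list[int] = []
    att_delta: list[float] = []
    att_accepted: list[bool] = []
    round_trips = np.zeros(n_rep, dtype=np.int64)
    # -1: last extreme was the top; +1: bottom; 0: none yet
    trip_phase = np.zeros(n_rep, dtype=np.int64)
    snapshots: list[tuple[int, int, Any]] = []

    attempt_parity = 0
    row = 0
    for sweep in range(config.n_sweeps):
        for r in range(n_rep):
            rng = rngs[r]
            t = temps[temp_of_replica[r]]
            beta = betas[temp_of_replica[r]]
            state, e_cur, lwc_cur = states[r], energies[r], lwcs[r]
            for _ in range(moves):
                proposal = model.propose(state, rng)
                e_new = model.energy(proposal)
                if not np.isfinite(e_new):
                    raise RuntimeError(
                        f"non-finite energy in replica {r} at sweep {sweep} "
                        f"(T = {t:g}); aborting"
                    )
                log_acc = -beta * (e_new - e_cur)
                if has_lwc:
                    lwc_new = model.log_weight_correction(proposal)
                    log_acc += lwc_new - lwc_cur
                else:
                    lwc_new = 0.0
                if rng.random() < math.exp(min(0.0, log_acc)):
                    state, e_cur, lwc_cur = proposal, e_new, lwc_new
            states[r], energies[r], lwcs[r] = state, e_cur, lwc_cur

            obs = model.observe(state)
            cols["sweep"][row] = sweep
            cols["replica_id"][row] = r
            cols["temp_index"][row] = temp_of_replica[r]
            cols["temperature"][row] = t
            cols["energy"][row] = e_cur
            for key in obs_keys:
                cols[key][row] = obs[key]
            row += 1

        temp_index_by_sweep[sweep] = temp_of_replica
        if config.state_interval and sweep % config.state_interval == 0:
            for r in range(n_rep):
                snapshots.append((sweep, int(temp_of_replica[r]), _copy_state(states[r])))

        if (sweep + 1) % config.exchange_interval == 0:
            for t_idx in range(attempt_parity, n_rep - 1, 2):
                ri = replica_at_temp[t_idx]
                rj = replica_at_temp[t_idx + 1]
                delta = (betas[t_idx] - betas[t_idx + 1]) * (energies[ri] - energies[rj])
                u = rng_ex.random()  # always drawn: stream advance is attempt-count only
                accepted = u < math.exp(min(0.0, delta))
                att_sweep.append(sweep)
                att_pair.append(t_idx)
                att_delta.append(float(delta))
                att_accepted.append(bool(accepted))
                if accepted:
                    temp_of_replica[ri], temp_of_replica[rj] = t_idx + 1, t_idx
                    replica_at_temp[t_idx], replica_at_temp[t_idx + 1] = rj, ri
            attempt_parity ^= 1

            # round-trip accounting at the ladder extremes
            for r in range(n_rep):
                if temp_of_replica[r] == 0:
                    if trip_phase[r] == -1:
                        round_trips[r] += 1
                    trip_phase[r] = 1
                elif temp_of_replica[r] == n_rep - 1:
                    trip_phase[r] = -1

    record = RexRecord(
        temperatures=temps.copy(),
        temp_index_by_sweep=temp_index_by_sweep,
        attempt_sweep=np.array(att_sweep, dtype=np.int64),
        attempt_pair=np.array(att_pair, dtype=np.int64),
        attempt_delta=np.array(att_delta, dtype=float),
        attempt_accepted=np.array(att_accepted, dtype=bool),
        round_trips=round_trips,
    )
    observables = pd.DataFrame(cols)
    return RexResult(
        record=record,
        observables=observables,
        final_states=states,
        state_snapshots=snapshots,
        config=config,
    )


def _copy_state(state: Any) -> Any:
    if isinstance(state, np.ndarray):
        return state.copy()
    return state


def run_mc(model: Any, temperature: float, config: RunConfig) -> RexResult:
    """Plain single-temperature Metropolis MC (a one-replica REX run)."""
    ladder = TemperatureLadder(np.array([float(temperature)]))
    return run_rex(model, ladder, config)
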