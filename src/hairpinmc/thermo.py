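"""Two-state folding thermodynamics estimators.

Frames are classified by the number of native backbone H-bonds:
folded when ``N_HB >= 4``, unfolded when ``N_HB <= 1``; frames in between
are intermediates and enter neither population.  From the production
ensemble at temperature T:

* ``delta_g = -kb T ln(Pf / Pu)`` — folding free energy;
* ``delta_u`` — folded-minus-unfolded mean potential energy, total and per
  energy component (component values sum to the total);
* ``delta_s = (delta_u - delta_g) / T`` — an identity by construction;
* ``Tm`` — the temperature where ``Pf = Pu``, located by linear
  interpolation of ``delta_g`` (falling back to ``Pf - Pu``) between the
  bracketing ladder temperatures.

When the unfolded state is essentially unpopulated (fewer unfolded frames
than a configurable floor) the estimators switch to a *folded-dominated*
mode: ``Pu`` is replaced by ``1 - Pf`` in the free energy and the
sub-ensemble energy difference is flagged as not directly estimable.

Statistical uncertainties follow the half-split convention: each estimate
is recomputed on the first and second halves of the production window and
the standard error is half the absolute difference.  ``batch_se`` provides
an alternative batch-means error used where a more stable uncertainty is
needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .constants import R_KCAL

__all__ = [
    "FOLDED_THRESHOLD",
    "UNFOLDED_THRESHOLD",
    "classify",
    "classify_series",
    "delta_g",
    "delta_g_from_folded_fraction",
    "delta_u",
    "delta_s",
    "combine_components",
    "TmEstimate",
    "melting_temperature",
    "half_split_se",
    "batch_se",
    "ThermoConfig",
    "ThermoResult",
    "analyze_thermo",
]

FOLDED_THRESHOLD = 4
UNFOLDED_THRESHOLD = 1


def classify(
    n_hb: int,
    folded_threshold: int = FOLDED_THRESHOLD,
    unfolded_threshold: int = UNFOLDED_THRESHOLD,
) -> str:
    """State label for one frame: ``folded``, ``unfolded`` or ``intermediate``."""
    if unfolded_threshold >= folded_threshold:
        raise ValueError(
            f"unfolded_threshold ({unfolded_threshold}) must be below "
            f"folded_threshold ({folded_threshold})"
        )
    if n_hb >= folded_threshold:
        return "folded"
    if n_hb <= unfolded_threshold:
        return "unfolded"
    return "intermediate"


def classify_series(
    n_hb: np.ndarray | pd.Series,
    folded_threshold: int = FOLDED_THRESHOLD,
    unfolded_threshold: int = UNFOLDED_THRESHOLD,
) -> np.ndarray:
    """Vectorized :func:`classify` returning an array of labels."""
    if unfolded_threshold >= folded_threshold:
        raise ValueError("unfolded_threshold must be below folded_threshold")
    n = np.asarray(n_hb)
    labels = np.full(n.shape, "intermediate", dtype=object)
    labels[n >= folded_threshold] = "folded"
    labels[n <= unfolded_threshold] = "unfolded"
    return labels


def delta_g(pf: float, pu: float, temperature: float, kb: float = R_KCAL) -> float:
    """Folding free energy ``-kb T ln(Pf/Pu)``.

    Antisymmetric under swapping the populations.  Zero populations are an
    error: use the folded-dominated mode
    (:func:`delta_g_from_folded_fraction`) when the unfolded state is not
    sampled.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if pf <= 0 or pu <= 0:
        raise ValueError(
            "both populations must be positive; for a folded-dominated "
            "ensemble use delta_g_from_folded_fraction (Pu = 1 - Pf)"
        )
    return -kb * temperature * math.log(pf / pu)


def delta_g_from_folded_fraction(
    pf: float, temperature: float, kb: float = R_KCAL
) -> float:
    """Free energy from a folded fraction alone: ``-kb T ln(pf/(1-pf))``.

    This is the estimator used for experimental folded populations and for
    folded-dominated simulation ensembles where the unfolded minimum is
    absent.
    """
    if not 0 < pf < 1:
        raise ValueError("folded fraction must be strictly between 0 and 1")
    return delta_g(pf, 1.0 - pf, temperature, kb)


def delta_u(
    ensemble: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    energy_column: str = "energy",
    component_prefix: str = "e_",
) -> tuple[float, dict[str, float]]:
    """Folded-minus-unfolded mean potential energy, total and per component.

    Intermediate frames are excluded.  Component entries (columns starting
    with ``component_prefix``) sum to the total up to round-off when the
    component columns decompose the energy column.
    """
    labels = np.asarray(labels)
    folded = ensemble[labels == "folded"]
    unfolded = ensemble[labels == "unfolded"]
    if len(folded) == 0 or len(unfolded) == 0:
        raise ValueError(
            "both sub-ensembles must be non-empty; for a folded-dominated "
            "ensemble delta_u is not directly estimable"
        )
    total = float(folded[energy_column].mean() - unfolded[energy_column].mean())
    components = {
        col[len(component_prefix):]: float(folded[col].mean() - unfolded[col].mean())
        for col in ensemble.columns
        if col.startswith(component_prefix)
    }
    return total, components


def delta_s(du: float, dg: float, temperature: float) -> float:
    """Folding entropy ``(delta_u - delta_g) / T`` in energy units per
    temperature unit (multiply by 1000 for cal/mol/K from kcal/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return (du - dg) / temperature


def combine_components(
    components: dict[str, float], groups: dict[str, tuple[str, ...]]
) -> dict[str, float]:
    """Sum named energy components into combined terms.

    Example: ``combine_components(dU, {"elec_gb": ("elec", "gb")})`` forms
    the screened-electrostatics total from the Coulomb and generalized-Born
    parts.
    """
    out = {}
    for name, members in groups.items():
        missing = [m for m in members if m not in components]
        if missing:
            raise KeyError(f"components {missing} not present for group {name!r}")
        out[name] = float(sum(components[m] for m in members))
    return out


@dataclass
class TmEstimate:
    """Melting temperature or a bound when no crossing is bracketed.

    ``value`` is None when the crossing lies outside the ladder, in which
    case ``bound`` is e.g. ``"<270"`` or ``">400"``.
    """

    value: float | None
    bound: str | None = None

    def __str__(self) -> str:
        return self.bound if self.value is None else f"{self.value:.4g}"


def melting_temperature(
    temperatures: np.ndarray,
    pf: np.ndarray,
    pu: np.ndarray,
    delta_gs: np.ndarray | None = None,
) -> TmEstimate:
    """Temperature where ``Pf = Pu``.

    Linear interpolation between the bracketing ladder temperatures, using
    ``delta_g`` values where finite (``Pf - Pu`` otherwise).  An exact hit
    at a ladder temperature returns that temperature.  With no crossing a
    bound is returned; with several crossings the lowest is returned with a
    warning.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    pf = np.asarray(pf, dtype=float)
    pu = np.asarray(pu, dtype=float)
    if temperatures.size < 2:
        # A single temperature cannot bracket a crossing: report a bound.
        s = pf[0] - pu[0]
        if s == 0:
            return TmEstimate(float(temperatures[0]))
        return TmEstimate(None, f">{temperatures[0]:g}" if s > 0 else f"<{temperatures[0]:g}")
    order = np.argsort(temperatures)
    temperatures, pf, pu = temperatures[order], pf[order], pu[order]
    signal = pf - pu
    if delta_gs is not None:
        delta_gs = np.asarray(delta_gs, dtype=float)[order]

    crossings: list[float] = []
    for i in range(temperatures.size):
        if signal[i] == 0.0:
            crossings.append(float(temperatures[i]))
    for i in range(temperatures.size - 1):
        s0, s1 = signal[i], signal[i + 1]
        if s0 * s1 < 0:
            # interpolate on delta_g when available and finite, else on Pf-Pu
            y0, y1 = None, None
            if delta_gs is not None and np.isfinite(delta_gs[i]) and np.isfinite(delta_gs[i + 1]):
                y0, y1 = -delta_gs[i], -delta_gs[i + 1]  # same sign convention as Pf-Pu
            else:
                y0, y1 = s0, s1
            t = temperatures[i] + (temperatures[i + 1] - temperatures[i]) * y0 / (y0 - y1)
            crossings.append(float(t))
    if not crossings:
        if signal[0] < 0:
            return TmEstimate(None, f"<{temperatures[0]:g}")
        return TmEstimate(None, f">{temperatures[-1]:g}")
    crossings = sorted(set(crossings))
    if len(crossings) > 1:
        warnings.warn(
            f"multiple Pf = Pu crossings at {crossings}; returning the lowest",
            stacklevel=2,
        )
    return TmEstimate(crossings[0])


def half_split_se(
    estimate_fn: Callable[[pd.DataFrame], float], production_ensemble: pd.DataFrame
) -> float | None:
    """Half-split standard error: |estimate(first half) - estimate(second
    half)| / 2, or None when the estimate is undefined on a half."""
    n = len(production_ensemble)
    if n < 2:
        return None
    half1 = production_ensemble.iloc[: n // 2]
    half2 = production_ensemble.iloc[n // 2 :]
    try:
        e1 = estimate_fn(half1)
        e2 = estimate_fn(half2)
    except (ValueError, ZeroDivisionError):
        return None
    if e1 is None or e2 is None or not (np.isfinite(e1) and np.isfinite(e2)):
        return None
    return abs(e1 - e2) / 2.0


def batch_se(
    estimate_fn: Callable[[pd.DataFrame], float],
    production_ensemble: pd.DataFrame,
    n_batches: int = 20,
) -> float | None:
    """Batch-means standard error over ``n_batches`` contiguous batches."""
    n = len(production_ensemble)
    if n < 2 * n_batches:
        return None
    estimates = []
    edges = np.linspace(0, n, n_batches + 1, dtype=int)
    for lo, hi in zip(edges[:-1], edges[1:]):
        try:
            e = estimate_fn(production_ensemble.iloc[lo:hi])
        except (ValueError, ZeroDivisionError):
            return None
        if e is None or not np.isfinite(e):
            return None
        estimates.append(e)
    return float(np.std(estimates, ddof=1) / math.sqrt(n_batches))


@dataclass
class ThermoConfig:
    """Estimator settings."""

    folded_threshold: int = FOLDED_THRESHOLD
    unfolded_threshold: int = UNFOLDED_THRESHOLD
    unfolded_floor: int = 10     # below this unfolded-frame count: folded-dominated
    kb: float = R_KCAL
    units: str = "physical"


@dataclass
class ThermoResult:
    """Folding thermodynamics at one temperature.

    ``delta_s`` is in energy units per temperature unit; in physical mode
    ``delta_s_cal`` gives cal/mol/K.  The identity
    ``delta_s == (delta_u_total - delta_g) / T`` holds by construction in
    two-state mode.
    """

    temperature: float
    mode: str                       # "two_state" | "folded_dominated"
    pf: float
    pu: float
    delta_g: float | None
    delta_u_total: float | None
    delta_u_components: dict[str, float] = field(default_factory=dict)
    delta_s: float | None = None
    se: dict[str, float | None] = field(default_factory=dict)
    n_frames: int = 0
    n_folded: int = 0
    n_unfolded: int = 0
    units: str = "physical"

    @property
    def delta_s_cal(self) -> float | None:
        """Entropy in cal/mol/K (physical mode only)."""
        if self.delta_s is None:
            return None
        if self.units != "physical":
            raise ValueError("delta_s_cal is defined in physical units only")
        return self.delta_s * 1000.0


def _analyze_one(
    ensemble: pd.DataFrame, temperature: float, config: ThermoConfig
) -> ThermoResult:
    labels = classify_series(
        ensemble["n_hb"], config.folded_threshold, config.unfolded_threshold
    )
    n = len(ensemble)
    n_f = int((labels == "folded").sum())
    n_u = int((labels == "unfolded").sum())
    pf, pu = n_f / n, n_u / n
    folded_dominated = n_u < config.unfolded_floor and n_f > n_u

    def _dg(df: pd.DataFrame) -> float:
        lab = classify_series(df["n_hb"], config.folded_threshold, config.unfolded_threshold)
        m = len(df)
        f, u = (lab == "folded").sum() / m, (lab == "unfolded").sum() / m
        if folded_dominated:
            return delta_g_from_folded_fraction(f, temperature, config.kb)
        return delta_g(f, u, temperature, config.kb)

    def _du(df: pd.DataFrame) -> float:
        lab = classify_series(df["n_hb"], config.folded_threshold, config.unfolded_threshold)
        return delta_u(df, lab)[0]

    def _pf(df: pd.DataFrame) -> float:
        lab = classify_series(df["n_hb"], config.folded_threshold, config.unfolded_threshold)
        return (lab == "folded").sum() / len(df)

    se: dict[str, float | None] = {}
    se["pf"] = half_split_se(_pf, ensemble)
    if folded_dominated:
        dg = (
            delta_g_from_folded_fraction(pf, temperature, config.kb)
            if 0 < pf < 1
            else None
        )
        se["delta_g"] = half_split_se(_dg, ensemble) if dg is not None else None
        result = ThermoResult(
            temperature=temperature,
            mode="folded_dominated",
            pf=pf,
            pu=1.0 - pf,
            delta_g=dg,
            delta_u_total=None,
            delta_u_components={},
            delta_s=None,
            se={**se, "delta_u": None, "delta_s": None},
            n_frames=n,
            n_folded=n_f,
            n_unfolded=n_u,
            units=config.units,
        )
        return result

    dg = delta_g(pf, pu, temperature, config.kb) if (pf > 0 and pu > 0) else None
    if n_f > 0 and n_u > 0:
        du_total, du_comps = delta_u(ensemble, labels)
    else:
        du_total, du_comps = None, {}
    ds = delta_s(du_total, dg, temperature) if (dg is not None and du_total is not None) else None
    se["delta_g"] = half_split_se(_dg, ensemble) if dg is not None else None
    se["delta_u"] = half_split_se(_du, ensemble) if du_total is not None else None
    if se["delta_g"] is not None and se["delta_u"] is not None:
        # propagate the half-split convention through the identity
        def _ds(df: pd.DataFrame) -> float:
            return delta_s(_du(df), _dg(df), temperature)

        se["delta_s"] = half_split_se(_ds, ensemble)
    else:
        se["delta_s"] = None
    return ThermoResult(
        temperature=temperature,
        mode="two_state",
        pf=pf,
        pu=pu,
        delta_g=dg,
        delta_u_total=du_total,
        delta_u_components=du_comps,
        delta_s=ds,
        se=se,
        n_frames=n,
        n_folded=n_f,
        n_unfolded=n_u,
        units=config.units,
    )


def analyze_thermo(
    observables: pd.DataFrame, config: ThermoConfig | None = None
) -> tuple[list[ThermoResult], TmEstimate]:
    """Full thermodynamic analysis of per-temperature production ensembles.

    ``observables`` must carry ``temperature``, ``n_hb`` and ``energy``
    columns (plus optional ``e_*`` component columns), with the production
    window already applied.  Returns one :class:`ThermoResult` per
    temperature (ascending) and the melting-temperature estimate.
    """
    config = config or ThermoConfig()
    if len(observables) == 0:
        raise ValueError("empty production ensemble")
    results = []
    for temperature, group in observables.groupby("temperature", sort=True):
        results.append(_analyze_one(group.reset_index(drop=True), float(temperature), config))
    temps = np.array([r.temperature for r in results])
    pf = np.array([r.pf for r in results])
    pu = np.array([r.pu for r in results])
    dgs = np.array(
        [r.delta_g if r.delta_g is not None else np.nan for r in results]
    )
    tm = melting_temperature(temps, pf, pu, dgs)
    return results, tm
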