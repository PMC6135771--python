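"""Physical constants and unit conventions.

Two unit modes are used throughout the package:

* ``physical`` — energies in kcal/mol, temperatures in Kelvin, distances in
  Angstrom. The gas constant is ``R_KCAL`` below.
* ``reduced`` — k_B = 1; energies and temperatures share one arbitrary unit.
  Used by the toy models (zipper, harmonic) where exact closed forms are
  compared against sampling.
"""

# Gas constant in kcal / mol / K.  The value is fixed here (rather than taken
# from scipy.constants at run time) so that numbers are stable across
# dependency versions.
R_KCAL: float = 1.987204e-3

# Boltzmann constant in reduced units.
KB_REDUCED: float = 1.0


def boltzmann_constant(units: str) -> float:
    """Return k_B for a unit mode (``"physical"`` or ``"reduced"``)."""
    if units == "physical":
        return R_KCAL
    if units == "reduced":
        return KB_REDUCED
    raise ValueError(f"unknown unit mode {units!r}; expected 'physical' or 'reduced'")
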