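"""Mole fractions and osmotic pressure under the ideal and free-solvent models.

Two composition variables drive everything here. The *total* water mole
fraction x1 counts every water molecule and every dissociated ion. The
*free* water mole fraction x̂1 first hands each macromolecule its bound
water and bound salt, then counts what is left — with the hydrated
macromolecule as a single particle. The osmotic pressure follows the
van-Laar form

    π = -(RT / V̄1) ln(x1_II / x1_I)

with x1 (ideal) or x̂1 (free-solvent) as the composition variable.

Numerical note: the chamber ratio is extremely close to 1 in dilute
solutions, so ``ln(x_II / x_I)`` evaluated in floating point loses most of
its relative accuracy to cancellation. The pressure routines therefore
form ``x_II/x_I − 1`` with exact rational arithmetic on the mole
inventories and finish with ``log1p``, keeping π accurate to a few ulp at
any concentration.
"""

from __future__ import annotations

import math
from fractions import Fraction

from .composition import (
    BindingMatrix,
    ChamberComposition,
    EMPTY_BINDING,
    ThermoConditions,
)
from .exceptions import InfeasibleBindingError, ValidationError

#: Pressure-unit conversion factors to Pa.
PRESSURE_UNITS = {
    "Pa": 1.0,
    "kPa": 1000.0,
    "atm": 101325.0,
    "mmHg": 133.322,
    "psi": 6894.757,
}


def convert_pressure(value, from_unit: str = "Pa", to_unit: str = "Pa"):
    """Convert pressures between Pa, kPa, atm, mmHg and psi."""
    try:
        f, t = PRESSURE_UNITS[from_unit], PRESSURE_UNITS[to_unit]
    except KeyError as e:
        raise ValidationError(
            f"unknown pressure unit {e.args[0]!r}; known: {sorted(PRESSURE_UNITS)}"
        ) from None
    return value * (f / t)


def _total_parts(comp: ChamberComposition) -> tuple[Fraction, Fraction]:
    """(numerator, denominator) of x1 as exact rationals of the stored moles."""
    n1 = Fraction(comp.solvent_moles)
    if not n1 > 0:
        raise ValidationError("composition has no solvent moles")
    total = n1
    for n in comp.proteins().values():
        total += Fraction(n)
    for sid, n in comp.salts().items():
        total += comp.species[sid].dissociation_count * Fraction(n)
    return n1, total


def _free_parts(
    comp: ChamberComposition, binding: BindingMatrix
) -> tuple[Fraction, Fraction]:
    """(numerator, denominator) of x̂1, validating binding feasibility."""
    n1 = Fraction(comp.solvent_moles)
    if not n1 > 0:
        raise ValidationError("composition has no solvent moles")
    proteins = comp.proteins()

    bound_water = sum(
        (Fraction(binding.get(comp.solvent_id, pid)) * Fraction(n)
         for pid, n in proteins.items()),
        Fraction(0),
    )
    free_water = n1 - bound_water
    if proteins and free_water <= 0:
        raise InfeasibleBindingError(comp.solvent_id, float(bound_water), float(n1))

    denom = free_water
    for n in proteins.values():
        denom += Fraction(n)
    for sid, n in comp.salts().items():
        d = comp.species[sid].dissociation_count
        bound = sum(
            (Fraction(binding.get(sid, pid)) * Fraction(nj)
             for pid, nj in proteins.items()),
            Fraction(0),
        )
        if not binding.salt_in_formula_units:
            bound = bound / d  # ν was given in ion-moles
        if bound > Fraction(n):
            raise InfeasibleBindingError(sid, float(bound), float(n))
        denom += d * (Fraction(n) - bound)
    return free_water, denom


def total_water_mole_fraction(comp: ChamberComposition) -> float:
    """x1: solvent moles over all particle moles, ions counted dissociated."""
    num, den = _total_parts(comp)
    return float(num / den)


def free_water_mole_fraction(
    comp: ChamberComposition, binding: BindingMatrix = EMPTY_BINDING
) -> float:
    """x̂1: free water over free particles plus hydrated-macromolecule moles.

    Bound water and bound salt are removed from both numerator and
    denominator; each macromolecule still counts as one particle (the
    hydrated complex). With zero binding, or in a protein-free chamber,
    this reduces to :func:`total_water_mole_fraction`.

    Raises
    ------
    InfeasibleBindingError
        If bound moles of any diffusible species exceed the moles
        available — the saturation boundary of the model.
    """
    num, den = _free_parts(comp, binding)
    return float(num / den)


def _pressure_from_parts(num2, den2, num1, den1, cond: ThermoConditions) -> float:
    """π = -(RT/V̄1) ln((num2/den2) / (num1/den1)), cancellation done exactly."""
    delta = (num2 * den1 - num1 * den2) / (num1 * den2)
    return -cond.rt_over_v1 * math.log1p(float(delta))


def osmotic_pressure_ideal(
    comp_II: ChamberComposition,
    comp_I: ChamberComposition,
    cond: ThermoConditions,
) -> float:
    """Ideal-solution osmotic pressure, π = -(RT/V̄1) ln(x1_II / x1_I), in Pa."""
    num2, den2 = _total_parts(comp_II)
    num1, den1 = _total_parts(comp_I)
    return _pressure_from_parts(num2, den2, num1, den1, cond)


def osmotic_pressure_freesolvent(
    comp_II: ChamberComposition,
    comp_I: ChamberComposition,
    binding: BindingMatrix,
    cond: ThermoConditions,
) -> float:
    """Free-solvent osmotic pressure, π = -(RT/V̄1) ln(x̂1_II / x̂1_I), in Pa."""
    num2, den2 = _free_parts(comp_II, binding)
    num1, den1 = _free_parts(comp_I, binding)
    return _pressure_from_parts(num2, den2, num1, den1, cond)


def osmotic_pressure_single_protein(
    n1_ii: float,
    n2: float,
    n3_ii: float,
    n1_i: float,
    n3_i: float,
    nu12: float,
    nu32: float,
    cond: ThermoConditions,
    dissociation: int = 2,
) -> float:
    """Closed form for one macromolecule in a single monovalent-salt solution.

    Hand-coded specialization of the general chamber-II mole-fraction
    bookkeeping, kept as an independent code path for cross-checking:

        x̂1_II = (N1 - ν12 N2) / [(N1 - ν12 N2) + N2 + d (N3 - ν32 N2)]
        x̂1_I  = N1_I / (N1_I + d N3_I)
        π = -(RT/V̄1) ln(x̂1_II / x̂1_I)
    """
    n1_ii, n2, n3_ii = Fraction(n1_ii), Fraction(n2), Fraction(n3_ii)
    n1_i, n3_i = Fraction(n1_i), Fraction(n3_i)
    free_w = n1_ii - Fraction(nu12) * n2
    if n2 > 0 and free_w <= 0:
        raise InfeasibleBindingError("water", float(Fraction(nu12) * n2), float(n1_ii))
    free_salt = n3_ii - Fraction(nu32) * n2
    if free_salt < 0:
        raise InfeasibleBindingError("salt", float(Fraction(nu32) * n2), float(n3_ii))
    den2 = free_w + n2 + dissociation * free_salt
    den1 = n1_i + dissociation * n3_i
    return _pressure_from_parts(free_w, den2, n1_i, den1, cond)
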