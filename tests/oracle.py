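"""Independent high-precision oracle for the osmotic-pressure math.

Re-derives mole fractions with exact rational arithmetic
(``fractions.Fraction`` — exact for any float input) and takes the
logarithm with ``decimal`` at 50 significant digits. Entirely separate
from the package's float implementation; used to freeze expected values
and to bound its rounding error.
"""

from __future__ import annotations

from decimal import Decimal, getcontext
from fractions import Fraction

getcontext().prec = 50


def prep_moles_exact(conc, protein_molar_mass, salt_molarity, vbar, rho, mw, volume=1):
    """Exact (N1, N2, N3) from the bench-prep bookkeeping."""
    conc = Fraction(conc)
    n2 = conc * Fraction(volume) / Fraction(protein_molar_mass)
    n3 = Fraction(salt_molarity) * Fraction(volume)
    n1 = (
        Fraction(rho)
        * (1000 - conc * Fraction(vbar))
        * Fraction(volume)
        / Fraction(mw)
    )
    return n1, n2, n3


def x_total_exact(n1, n2, n3, dissociation=2) -> Fraction:
    n1, n2, n3 = Fraction(n1), Fraction(n2), Fraction(n3)
    return n1 / (n1 + n2 + dissociation * n3)


def x_free_exact(n1, n2, n3, nu12, nu32, dissociation=2) -> Fraction:
    n1, n2, n3 = Fraction(n1), Fraction(n2), Fraction(n3)
    nu12, nu32 = Fraction(nu12), Fraction(nu32)
    free_w = n1 - nu12 * n2
    if n2 > 0 and free_w <= 0:
        raise ValueError("infeasible water binding")
    free_salt = n3 - nu32 * n2
    if free_salt < 0:
        raise ValueError("infeasible salt binding")
    return free_w / (free_w + n2 + dissociation * free_salt)


def _dec(x) -> Decimal:
    if isinstance(x, Fraction):
        return Decimal(x.numerator) / Decimal(x.denominator)
    return Decimal(x)


def pressure_exact(x_ii, x_i, gas_constant, temperature, v1) -> float:
    """π = -(RT/V1) ln(x_II / x_I) at 50-digit precision."""
    ratio = _dec(x_ii) / _dec(x_i)
    rt_v1 = _dec(gas_constant) * _dec(temperature) / _dec(v1)
    return float(-rt_v1 * ratio.ln())


def gamma_exact(n1_ii, n2, n3_ii, n1_i, n3_i, nu12, nu32, dissociation=2) -> float:
    """γ1 = (x̂_II / x_II) · (x_I / x̂_I), exact rational arithmetic."""
    g = (
        x_free_exact(n1_ii, n2, n3_ii, nu12, nu32, dissociation)
        / x_total_exact(n1_ii, n2, n3_ii, dissociation)
    ) * (
        x_total_exact(n1_i, 0, n3_i, dissociation)
        / x_free_exact(n1_i, 0, n3_i, 0, 0, dissociation)
    )
    return float(_dec(g))
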