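"""Mole fractions and osmotic pressure: identities, limits, oracle checks."""

import math

import numpy as np
import pytest

from freesolvent import (
    BindingMatrix,
    ChamberComposition,
    InfeasibleBindingError,
    Species,
    ThermoConditions,
    convert_pressure,
    free_water_mole_fraction,
    osmotic_pressure_freesolvent,
    osmotic_pressure_ideal,
    osmotic_pressure_single_protein,
    total_water_mole_fraction,
)
from freesolvent.composition import BSA_MOLAR_MASS

from .conftest import random_feasible_case, system_for_case
from . import oracle

WATER = Species("water", "solvent", 18.015, 1)
NACL = Species("salt", "salt", 58.443, 2)
PROT = Species("macromolecule", "protein", BSA_MOLAR_MASS, 1)


def comp(n1, n2=0.0, n3=0.0, chamber="II"):
    species = {"water": WATER, "macromolecule": PROT, "salt": NACL}
    moles = {"water": n1, "macromolecule": n2, "salt": n3}
    if chamber == "I":
        moles.pop("macromolecule")
    return ChamberComposition(species=species, moles=moles, chamber=chamber)


class TestMoleFractions:
    def test_pure_water(self):
        assert total_water_mole_fraction(comp(55.35)) == 1.0

    def test_dissociated_salt_counted_twice(self):
        x = total_water_mole_fraction(comp(55.35, 0.0, 0.15))
        assert x == pytest.approx(55.35 / 55.65, rel=1e-15)

    def test_zero_binding_reduces_to_total(self):
        c = comp(50.0, 0.002, 0.1)
        assert free_water_mole_fraction(c, BindingMatrix()) == total_water_mole_fraction(c)

    def test_protein_free_chamber_reduces_to_total(self):
        c = comp(55.0, 0.0, 0.15, chamber="I")
        b = BindingMatrix(nu={("water", "macromolecule"): 3000.0})
        assert free_water_mole_fraction(c, b) == total_water_mole_fraction(c)

    def test_hand_worked_case(self):
        # 1 mol bound water, 0.005 mol bound salt formula units:
        # x̂ = 49 / (49 + 0.001 + 2*0.005)
        c = comp(50.0, 0.001, 0.01)
        b = BindingMatrix(
            nu={("water", "macromolecule"): 1000.0, ("salt", "macromolecule"): 5.0}
        )
        assert free_water_mole_fraction(c, b) == pytest.approx(
            49.0 / 49.011, rel=1e-14
        )

    def test_crowded_case_matches_exact_oracle(self):
        n1, n2, n3 = oracle.prep_moles_exact(300.0, BSA_MOLAR_MASS, 0.15, 0.733, 0.997, 18.015)
        c = comp(float(n1), float(n2), float(n3))
        x = total_water_mole_fraction(c)
        assert x == pytest.approx(float(oracle.x_total_exact(n1, n2, n3)), rel=1e-14)

    def test_overbinding_names_species(self):
        c = comp(50.0, 0.001, 0.01)
        b = BindingMatrix(nu={("salt", "macromolecule"): 50.0})
        with pytest.raises(InfeasibleBindingError, match="salt"):
            free_water_mole_fraction(c, b)
        b = BindingMatrix(nu={("water", "macromolecule"): 1e6})
        with pytest.raises(InfeasibleBindingError, match="water"):
            free_water_mole_fraction(c, b)


class TestOsmoticPressure:
    COND = ThermoConditions(temperature=298.15)

    def test_identical_chambers_zero(self):
        a = comp(55.0, 0.0, 0.15)
        b = comp(55.0, 0.0, 0.15, chamber="I")
        assert osmotic_pressure_ideal(a, b, self.COND) == pytest.approx(0.0, abs=1e-9)
        binding = BindingMatrix(nu={("water", "macromolecule"): 3000.0})
        assert osmotic_pressure_freesolvent(a, b, binding, self.COND) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_log_identity(self):
        # x_II/x_I = exp(-1) makes π exactly RT/V1
        n1 = 50.0
        a = comp(n1, n2=n1 * (math.e - 1.0))
        b = comp(n1, chamber="I")
        pi = osmotic_pressure_ideal(a, b, self.COND)
        assert pi == pytest.approx(self.COND.rt_over_v1, rel=1e-12)

    def test_vant_hoff_dilute_limit(self):
        # 1 g/L, no salt: within 1% of RT C / M
        case_sys = system_for_case(
            {
                "protein_molar_mass": BSA_MOLAR_MASS,
                "salt_molarity": 0.0,
                "temperature": 298.15,
            }
            | {"conc": 1.0, "hydration": 0.0, "ion_binding": 0.0}
        )
        ii, i = case_sys.chambers(1.0)
        pi = osmotic_pressure_ideal(ii, i, case_sys.conditions)
        vant_hoff = 8.314462618 * 298.15 * (1000.0 / BSA_MOLAR_MASS)
        assert abs(pi - vant_hoff) / vant_hoff <= 0.01

    def test_zero_binding_equals_ideal(self, rng):
        for _ in range(20):
            case = random_feasible_case(rng)
            sys_ = system_for_case(case)
            ii, i = sys_.chambers(case["conc"])
            assert osmotic_pressure_freesolvent(
                ii, i, BindingMatrix(), sys_.conditions
            ) == osmotic_pressure_ideal(ii, i, sys_.conditions)

    def test_monotone_in_concentration_and_binding(self, bsa_scenario):
        sys_ = bsa_scenario.system()
        concs = np.linspace(0.0, 450.0, 10)
        base_nu1 = bsa_scenario.hydration_mol_per_mol

        def pi(c, nu1, nu3):
            ii, i = sys_.chambers(c)
            return osmotic_pressure_freesolvent(
                ii, i, sys_.binding(nu1, nu3), sys_.conditions
            )

        curve = [pi(c, base_nu1, 11.59) for c in concs]
        assert all(b > a for a, b in zip(curve, curve[1:]))
        # more bound water -> larger pressure; more bound salt -> smaller
        at_300 = [pi(300.0, nu1, 11.59) for nu1 in (2000.0, 3000.0, base_nu1)]
        assert at_300[0] < at_300[1] < at_300[2]
        vs_nu3 = [pi(300.0, base_nu1, nu3) for nu3 in (0.0, 5.0, 11.59)]
        assert vs_nu3[0] > vs_nu3[1] > vs_nu3[2]

    def test_closed_form_matches_general_and_oracle(self, rng):
        cond = self.COND
        for _ in range(30):
            case = random_feasible_case(rng)
            sys_ = system_for_case(case)
            cond_case = sys_.conditions
            ii, i = sys_.chambers(case["conc"])
            binding = sys_.binding(case["hydration"], case["ion_binding"])
            general = osmotic_pressure_freesolvent(ii, i, binding, cond_case)
            closed = osmotic_pressure_single_protein(
                ii.solvent_moles,
                ii.moles_of("macromolecule"),
                ii.moles_of("salt"),
                i.solvent_moles,
                i.moles_of("salt"),
                case["hydration"],
                case["ion_binding"],
                cond_case,
            )
            assert closed == pytest.approx(general, rel=1e-12)
            x_ii = oracle.x_free_exact(
                ii.solvent_moles,
                ii.moles_of("macromolecule"),
                ii.moles_of("salt"),
                case["hydration"],
                case["ion_binding"],
            )
            x_i = oracle.x_free_exact(i.solvent_moles, 0.0, i.moles_of("salt"), 0, 0)
            exact = oracle.pressure_exact(
                x_ii, x_i, cond.gas_constant, case["temperature"],
                cond_case.solvent_partial_molar_volume,
            )
            assert general == pytest.approx(exact, rel=1e-12)


def test_pressure_unit_conversion():
    assert convert_pressure(760.0, "mmHg", "Pa") == pytest.approx(101325.0, rel=1e-4)
    assert convert_pressure(1.0, "atm", "mmHg") == pytest.approx(760.0, rel=1e-4)
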