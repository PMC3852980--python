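"""Shared fixtures: canonical solution systems and random feasible draws."""

from __future__ import annotations

import numpy as np
import pytest

from freesolvent import (
    Species,
    SolutionSystem,
    ThermoConditions,
    preset_scenarios,
)


@pytest.fixture(scope="session")
def scenarios():
    return preset_scenarios()


@pytest.fixture(scope="session")
def bsa_scenario(scenarios):
    return scenarios["bsa_ph4.5"]


@pytest.fixture(scope="session")
def bsa_system(bsa_scenario):
    return bsa_scenario.system()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_feasible_case(rng) -> dict:
    """One random single-protein/monovalent-salt osmometry setup.

    Concentrations span the crowded regime. Specific hydration is drawn in
    g/g (the scale on which globular proteins cluster near 1) so the bound
    water stays below the available water at every draw; ion binding is
    capped so bound salt stays below the chamber salt.
    """
    conc = float(rng.uniform(50.0, 450.0))
    molar_mass = float(rng.uniform(30000.0, 150000.0))
    salt_molarity = float(rng.uniform(0.05, 0.3))
    hydration_g_per_g = float(rng.uniform(0.5, 1.3))
    n2_max = conc / molar_mass  # basis 1 L
    nu3_cap = min(20.0, 0.9 * salt_molarity / n2_max)
    return {
        "conc": conc,
        "hydration": hydration_g_per_g * molar_mass / 18.015,
        "ion_binding": float(rng.uniform(0.0, nu3_cap)),
        "salt_molarity": salt_molarity,
        "temperature": float(rng.uniform(273.15, 310.15)),
        "protein_molar_mass": molar_mass,
    }


def system_for_case(case: dict) -> SolutionSystem:
    protein = Species("macromolecule", "protein", case["protein_molar_mass"], 1)
    salt = Species("salt", "salt", 58.443, 2)
    return SolutionSystem(
        protein=protein,
        conditions=ThermoConditions(temperature=case["temperature"]),
        salt=salt,
        salt_molarity=case["salt_molarity"],
    )
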