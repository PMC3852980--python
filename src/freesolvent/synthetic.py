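"""Synthetic membrane-osmometry datasets.

Generates (concentration, pressure) series from the free-solvent forward
model plus a seeded noise model, emulating classic single-macromolecule
osmometry series: BSA in 0.15 M NaCl at 25 °C over 0–475 g/L, sheep
hemoglobin in 0.1 M KCl at 0 °C, and sucrose in water at 30 °C. Every
stage of the package is testable against these with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .composition import (
    BSA_MOLAR_MASS,
    HB_MOLAR_MASS,
    KCL_MOLAR_MASS,
    NACL_MOLAR_MASS,
    SUCROSE_MOLAR_MASS,
    Species,
    SolutionSystem,
    ThermoConditions,
    hydration_g_per_g_to_mol_per_mol,
)
from .core import osmotic_pressure_freesolvent
from .dataset import OsmoticDataset
from .exceptions import FreeSolventError, ValidationError

NOISE_KINDS = ("none", "multiplicative_gaussian", "additive_gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the generator.

    ``scale`` is a relative fraction for multiplicative noise, Pa for
    additive. Identical seed + parameters reproduce the dataset exactly.
    """

    kind: str = "none"
    scale: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValidationError(f"noise kind must be one of {NOISE_KINDS}")
        if self.scale < 0:
            raise ValidationError("noise scale must be >= 0")

    def apply(self, pressures: np.ndarray) -> np.ndarray:
        if self.kind == "none" or self.scale == 0.0:
            return pressures.copy()
        rng = np.random.default_rng(self.seed)
        eps = rng.standard_normal(pressures.shape)
        if self.kind == "multiplicative_gaussian":
            return pressures * (1.0 + self.scale * eps)
        return pressures + self.scale * eps


def generate_osmotic_dataset(
    system: SolutionSystem,
    hydration_mol_per_mol: float,
    ion_binding: float = 0.0,
    conc_grid: Sequence[float] = (),
    noise: NoiseModel = NoiseModel(),
    provenance: str = "synthetic",
) -> OsmoticDataset:
    """Forward-model pressures on a concentration grid, plus noise.

    All concentrations must be feasible under the binding; offending rows
    are reported together in the raised error.
    """
    conc = np.asarray(list(conc_grid), dtype=float)
    binding = system.binding(hydration_mol_per_mol, ion_binding)
    comp_i = system.chamber(0.0, "I")
    pressures = np.empty(conc.shape)
    bad: list[tuple[int, str]] = []
    for k, c in enumerate(conc):
        try:
            comp_ii = system.chamber(float(c), "II")
            pressures[k] = osmotic_pressure_freesolvent(
                comp_ii, comp_i, binding, system.conditions
            )
        except FreeSolventError as exc:
            bad.append((k, str(exc)))
    if bad:
        rows = ", ".join(f"row {k} (conc={conc[k]:g} g/L): {msg}" for k, msg in bad)
        raise ValidationError(f"infeasible concentrations: {rows}")
    return OsmoticDataset(
        conc=conc,
        pressure_Pa=noise.apply(pressures),
        system=system,
        provenance=provenance,
    )


@dataclass(frozen=True)
class Scenario:
    """A ready-to-run osmometry configuration for one literature system."""

    name: str
    protein: Species
    temperature: float  # K
    salt: Optional[Species] = None
    salt_molarity: float = 0.0
    hydration_g_per_g: float = 0.0  # default (SASA-monolayer/GETAREA) value
    hydration_range_g_per_g: tuple = (0.0, 0.0)
    ion_binding: float = 0.0  # mol salt formula units / mol macromolecule
    partial_specific_volume: float = 0.733  # mL/g
    conc_grid: tuple = field(default_factory=tuple)  # g/L

    def system(self) -> SolutionSystem:
        return SolutionSystem(
            protein=self.protein,
            conditions=ThermoConditions(temperature=self.temperature),
            salt=self.salt,
            salt_molarity=self.salt_molarity,
            partial_specific_volume=self.partial_specific_volume,
        )

    @property
    def hydration_mol_per_mol(self) -> float:
        return hydration_g_per_g_to_mol_per_mol(
            self.hydration_g_per_g, self.protein.molar_mass
        )

    def generate(
        self,
        noise: NoiseModel = NoiseModel(),
        conc_grid: Optional[Sequence[float]] = None,
    ) -> OsmoticDataset:
        grid = self.conc_grid if conc_grid is None else conc_grid
        return generate_osmotic_dataset(
            self.system(),
            self.hydration_mol_per_mol,
            self.ion_binding,
            conc_grid=grid,
            noise=noise,
            provenance=f"synthetic:{self.name}",
        )


_PROTEIN_GRID = tuple(np.linspace(0.0, 475.0, 20))
_SUCROSE_GRID = tuple(np.linspace(0.0, 900.0, 20))


def preset_scenarios() -> dict[str, Scenario]:
    """The five canonical systems: BSA at three pH values, Hb, sucrose.

    Hydrations are SASA-monolayer values (15.2 waters/nm²); the default is
    the GETAREA-surface figure, with the cross-software range attached. Ion
    bindings are the published Scatchard-type (BSA/NaCl, pH-dependent) and
    Hb/KCl values. Sucrose binds no ions; its hydration range spans the
    literature 3.5–6 mol/mol.
    """
    bsa = Species("bsa", "protein", BSA_MOLAR_MASS, 1)
    hb = Species("hb", "protein", HB_MOLAR_MASS, 1)
    sucrose = Species("sucrose", "protein", SUCROSE_MOLAR_MASS, 1)
    nacl = Species("nacl", "salt", NACL_MOLAR_MASS, 2)
    kcl = Species("kcl", "salt", KCL_MOLAR_MASS, 2)

    def bsa_scenario(name: str, ion_binding: float) -> Scenario:
        return Scenario(
            name=name,
            protein=bsa,
            temperature=298.15,
            salt=nacl,
            salt_molarity=0.15,
            hydration_g_per_g=1.144,
            hydration_range_g_per_g=(1.144, 1.162),
            ion_binding=ion_binding,
            conc_grid=_PROTEIN_GRID,
        )

    return {
        "bsa_ph4.5": bsa_scenario("bsa_ph4.5", 11.59),
        "bsa_ph5.4": bsa_scenario("bsa_ph5.4", 10.62),
        "bsa_ph7.4": bsa_scenario("bsa_ph7.4", 8.81),
        "hb": Scenario(
            name="hb",
            protein=hb,
            temperature=273.15,
            salt=kcl,
            salt_molarity=0.1,
            hydration_g_per_g=0.973,
            hydration_range_g_per_g=(0.955, 1.025),
            ion_binding=6.0,
            conc_grid=_PROTEIN_GRID,
        ),
        "sucrose": Scenario(
            name="sucrose",
            protein=sucrose,
            temperature=303.15,
            hydration_g_per_g=0.316,
            hydration_range_g_per_g=(0.184, 0.316),
            ion_binding=0.0,
            partial_specific_volume=0.61,
            conc_grid=_SUCROSE_GRID,
        ),
    }
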