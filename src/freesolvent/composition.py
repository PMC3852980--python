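"""Species bookkeeping, hydration conversions and osmometer compositions.

The free-solvent picture of a concentrated macromolecule solution treats the
macromolecule together with its bound water and bound ions as a single
"hydrated macromolecule" species; the remaining, *free* solvent is then
ideal. This module holds the domain types shared across the package:
chemical species, thermodynamic conditions, the mole inventory of each
osmometer chamber, the binding stoichiometry, and the conversions between
the three ways hydration is quoted in the literature — a solvent-accessible
surface area (SASA) with a monolayer coverage, grams of water per gram of
macromolecule, and moles of water per mole of macromolecule.

Units: moles internally; SASA in Å²; coverage in waters/nm²; pressures are
handled elsewhere in Pa.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .exceptions import (
    InfeasibleCompositionError,
    ValidationError,
)

# Physical constants and reference molar masses (g/mol). The macromolecule
# masses are the full-precision values needed to reproduce published
# 3-decimal hydration figures; all are overridable wherever they are used.
GAS_CONSTANT = 8.314462618  # J/(mol K)
WATER_MOLAR_MASS = 18.015
WATER_DENSITY = 0.997  # g/mL at 25 C
MONOLAYER_COVERAGE = 15.2  # water molecules per nm^2 of SASA
BSA_MOLAR_MASS = 66430.0
HB_MOLAR_MASS = 69700.0
SUCROSE_MOLAR_MASS = 342.30
NACL_MOLAR_MASS = 58.443
KCL_MOLAR_MASS = 74.551

#: Partial molar volume of water (m^3/mol) implied by the default density.
WATER_MOLAR_VOLUME = WATER_MOLAR_MASS / WATER_DENSITY * 1e-6

ROLES = ("solvent", "protein", "salt")


def round_printed(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, matching how tabulated values are printed."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class Species:
    """A chemical species in the osmometer.

    ``dissociation_count`` is the number of osmotically active particles per
    formula unit: 1 for the solvent, macromolecules and non-electrolytes,
    2 for a monovalent salt such as NaCl or KCl.
    """

    id: str
    role: str
    molar_mass: float  # g/mol
    dissociation_count: int = 1

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"species {self.id!r}: role must be one of {ROLES}")
        if not self.molar_mass > 0:
            raise ValidationError(f"species {self.id!r}: molar_mass must be > 0")
        if int(self.dissociation_count) != self.dissociation_count or self.dissociation_count < 1:
            raise ValidationError(
                f"species {self.id!r}: dissociation_count must be a positive integer"
            )


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature and the solvent's partial molar volume, V1 (m^3/mol)."""

    temperature: float  # K
    solvent_partial_molar_volume: float = WATER_MOLAR_VOLUME
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValidationError("temperature must be > 0 K")
        if not self.solvent_partial_molar_volume > 0:
            raise ValidationError("solvent_partial_molar_volume must be > 0")

    @property
    def rt_over_v1(self) -> float:
        """R*T/V1 in Pa — the pressure scale of the osmotic law."""
        return self.gas_constant * self.temperature / self.solvent_partial_molar_volume


@dataclass(frozen=True)
class ChamberComposition:
    """Mole inventory N_i of one osmometer chamber on a basis volume.

    Chamber II holds the macromolecule; chamber I holds only diffusible
    species. The invariant "chamber I contains no protein" is enforced here.
    """

    species: Mapping[str, Species]
    moles: Mapping[str, float]
    chamber: str = "II"
    basis_volume: float = 1.0  # L

    def __post_init__(self):
        if self.chamber not in ("I", "II"):
            raise ValidationError("chamber must be 'I' or 'II'")
        if not self.basis_volume > 0:
            raise ValidationError("basis_volume must be > 0")
        unknown = set(self.moles) - set(self.species)
        if unknown:
            raise ValidationError(f"moles given for unknown species: {sorted(unknown)}")
        solvents = [s for s in self.species.values() if s.role == "solvent"]
        if len(solvents) != 1:
            raise ValidationError("a composition requires exactly one solvent species")
        for sid, n in self.moles.items():
            if n < 0:
                raise ValidationError(f"negative moles for species {sid!r}")
        if self.chamber == "I":
            for sid, n in self.moles.items():
                if n > 0 and self.species[sid].role == "protein":
                    raise ValidationError("chamber I must not contain protein")

    @property
    def solvent_id(self) -> str:
        return next(s.id for s in self.species.values() if s.role == "solvent")

    @property
    def solvent_moles(self) -> float:
        return float(self.moles.get(self.solvent_id, 0.0))

    def moles_of(self, sid: str) -> float:
        return float(self.moles.get(sid, 0.0))

    def proteins(self) -> dict[str, float]:
        return {
            sid: float(n)
            for sid, n in self.moles.items()
            if self.species[sid].role == "protein"
        }

    def salts(self) -> dict[str, float]:
        return {
            sid: float(n)
            for sid, n in self.moles.items()
            if self.species[sid].role == "salt"
        }

    def scaled(self, factor: float) -> "ChamberComposition":
        """Scale every mole count (and the basis volume) by ``factor``."""
        if not factor > 0:
            raise ValidationError("scale factor must be > 0")
        return replace(
            self,
            moles={k: v * factor for k, v in self.moles.items()},
            basis_volume=self.basis_volume * factor,
        )


@dataclass(frozen=True)
class BindingMatrix:
    """Binding stoichiometry ν_ij: moles of diffusible species ``i`` bound
    per mole of macromolecule ``j``.

    Salt binding is counted in formula units of undissociated salt
    (``salt_in_formula_units=True``, the convention of published
    mol NaCl/mol BSA values); a bound formula unit removes
    ``dissociation_count`` ion-moles from the free-ion count.
    """

    nu: Mapping[tuple, float] = field(default_factory=dict)
    salt_in_formula_units: bool = True

    def __post_init__(self):
        for (i, j), v in self.nu.items():
            if v < 0:
                raise ValidationError(f"nu[{i!r},{j!r}] must be >= 0")

    def get(self, diffusible_id: str, protein_id: str) -> float:
        return float(self.nu.get((diffusible_id, protein_id), 0.0))

    def bound_moles(self, diffusible_id: str, comp: ChamberComposition) -> float:
        """Total formula-unit moles of ``diffusible_id`` bound in ``comp``."""
        return sum(
            self.get(diffusible_id, pid) * n for pid, n in comp.proteins().items()
        )

    @property
    def is_zero(self) -> bool:
        return all(v == 0 for v in self.nu.values())


EMPTY_BINDING = BindingMatrix()


@dataclass(frozen=True)
class HydrationSpec:
    """Hydration of a macromolecule expressed in all its common units."""

    sasa: float  # Å²
    surface_coverage: float  # waters per nm²
    molar_hydration: float  # mol H2O / mol macromolecule
    specific_hydration: float  # g H2O / g macromolecule


def hydration_from_sasa(
    sasa: float,
    coverage: float = MONOLAYER_COVERAGE,
    macromolecule_molar_mass: float = BSA_MOLAR_MASS,
    water_molar_mass: float = WATER_MOLAR_MASS,
) -> HydrationSpec:
    """Monolayer hydration from a solvent-accessible surface area.

    A monolayer of ``coverage`` waters per nm² tiles the surface, so the
    molar hydration is ``(sasa Å² / 100) × coverage`` (1 nm² = 100 Å²).
    """
    if sasa < 0:
        raise ValidationError("sasa must be >= 0")
    if not coverage > 0:
        raise ValidationError("coverage must be > 0")
    if not (macromolecule_molar_mass > 0 and water_molar_mass > 0):
        raise ValidationError("molar masses must be > 0")
    molar = (sasa / 100.0) * coverage
    specific = hydration_mol_per_mol_to_g_per_g(
        molar, macromolecule_molar_mass, water_molar_mass
    )
    return HydrationSpec(
        sasa=sasa,
        surface_coverage=coverage,
        molar_hydration=molar,
        specific_hydration=specific,
    )


def hydration_g_per_g_to_mol_per_mol(
    h: float,
    macromolecule_molar_mass: float,
    water_molar_mass: float = WATER_MOLAR_MASS,
) -> float:
    """Convert specific hydration (g water / g macromolecule) to mol/mol."""
    if h < 0:
        raise ValidationError("hydration must be >= 0")
    return h * macromolecule_molar_mass / water_molar_mass


def hydration_mol_per_mol_to_g_per_g(
    h: float,
    macromolecule_molar_mass: float,
    water_molar_mass: float = WATER_MOLAR_MASS,
) -> float:
    """Convert molar hydration (mol water / mol macromolecule) to g/g."""
    if h < 0:
        raise ValidationError("hydration must be >= 0")
    return h * water_molar_mass / macromolecule_molar_mass


def composition_from_prep(
    protein_conc: float,
    protein: Optional[Species],
    salt_molarity: float,
    salt: Optional[Species],
    basis_volume: float = 1.0,
    protein_partial_specific_volume: float = 0.733,
    water_density: float = WATER_DENSITY,
    water_molar_mass: float = WATER_MOLAR_MASS,
    chamber: str = "II",
    solvent: Optional[Species] = None,
) -> ChamberComposition:
    """Mole inventory from a bench recipe (protein g/L, salt molarity).

    Water fills whatever part of the basis volume the protein does not
    exclude: ``N1 = ρ_w (1000 V − C V v̄_p) / M_w``; the salt's own volume
    is neglected. Chamber I is the same recipe with C = 0.
    """
    if protein_conc < 0:
        raise ValidationError("protein_conc must be >= 0")
    if salt_molarity < 0:
        raise ValidationError("salt_molarity must be >= 0")
    if protein_conc > 0 and protein is None:
        raise ValidationError("protein species required when protein_conc > 0")
    excluded_mL_per_L = protein_conc * protein_partial_specific_volume
    if protein_conc > 0 and excluded_mL_per_L >= 1000.0:
        raise InfeasibleCompositionError(
            f"protein volume {excluded_mL_per_L:.1f} mL/L meets or exceeds the "
            "basis volume; the recipe cannot exist"
        )
    if solvent is None:
        solvent = Species("water", "solvent", water_molar_mass, 1)
    species: dict[str, Species] = {solvent.id: solvent}
    moles: dict[str, float] = {}
    n1 = water_density * (1000.0 - excluded_mL_per_L) * basis_volume / water_molar_mass
    moles[solvent.id] = n1
    if protein is not None:
        species[protein.id] = protein
        moles[protein.id] = (
            protein_conc * basis_volume / protein.molar_mass if protein_conc > 0 else 0.0
        )
    if salt is not None:
        species[salt.id] = salt
        moles[salt.id] = salt_molarity * basis_volume
    if chamber == "I":
        # diffusible species only
        moles = {k: v for k, v in moles.items() if species[k].role != "protein"}
        species = {k: v for k, v in species.items() if k in moles}
    return ChamberComposition(
        species=species, moles=moles, chamber=chamber, basis_volume=basis_volume
    )


@dataclass(frozen=True)
class SolutionSystem:
    """A complete osmometry setup: one macromolecule in a (possibly salt-free)
    aqueous solution, with the constants needed to turn a g/L concentration
    into chamber compositions.
    """

    protein: Species
    conditions: ThermoConditions
    salt: Optional[Species] = None
    salt_molarity: float = 0.0
    partial_specific_volume: float = 0.733  # mL/g
    water_density: float = WATER_DENSITY  # g/mL
    water_molar_mass: float = WATER_MOLAR_MASS
    basis_volume: float = 1.0  # L

    def __post_init__(self):
        if self.protein.role != "protein":
            raise ValidationError("SolutionSystem.protein must have role 'protein'")
        if self.salt is not None and self.salt.role != "salt":
            raise ValidationError("SolutionSystem.salt must have role 'salt'")
        if self.salt_molarity < 0:
            raise ValidationError("salt_molarity must be >= 0")
        if self.salt_molarity > 0 and self.salt is None:
            raise ValidationError("salt species required when salt_molarity > 0")

    def chamber(self, protein_conc: float, chamber: str = "II") -> ChamberComposition:
        return composition_from_prep(
            protein_conc if chamber == "II" else 0.0,
            self.protein,
            self.salt_molarity,
            self.salt,
            basis_volume=self.basis_volume,
            protein_partial_specific_volume=self.partial_specific_volume,
            water_density=self.water_density,
            water_molar_mass=self.water_molar_mass,
            chamber=chamber,
        )

    def chambers(self, protein_conc: float):
        """(chamber II, chamber I) compositions for one protein concentration."""
        return self.chamber(protein_conc, "II"), self.chamber(0.0, "I")

    def binding(self, hydration_mol_per_mol: float, ion_binding: float = 0.0) -> BindingMatrix:
        """Binding matrix for this system's single macromolecule."""
        nu: dict[tuple, float] = {("water", self.protein.id): hydration_mol_per_mol}
        if self.salt is not None:
            nu[(self.salt.id, self.protein.id)] = ion_binding
        elif ion_binding:
            raise ValidationError("ion_binding given but the system has no salt")
        return BindingMatrix(nu=nu)
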