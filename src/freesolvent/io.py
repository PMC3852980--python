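"""Configuration and dataset I/O.

Datasets are plain CSV (comma-separated, UTF-8, header required) with
columns ``conc_g_per_L``, ``pressure`` and optionally ``pressure_unit``;
configurations are YAML (JSON is valid YAML and accepted) validated by a
strict pydantic schema — unknown keys are rejected with the offending name.
Everything is normalized to Pa / K / mol internally.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import pydantic
import yaml

from .composition import (
    Species,
    SolutionSystem,
    ThermoConditions,
    WATER_DENSITY,
    WATER_MOLAR_MASS,
    hydration_from_sasa,
    hydration_g_per_g_to_mol_per_mol,
)
from .core import PRESSURE_UNITS, convert_pressure
from .dataset import OsmoticDataset
from .exceptions import DatasetError, ValidationError

log = logging.getLogger("freesolvent")


# -- dataset CSV ---------------------------------------------------------


def read_dataset(
    path,
    pressure_unit: Optional[str] = None,
    system: Optional[SolutionSystem] = None,
) -> OsmoticDataset:
    """Read an osmometry CSV; pressures are converted to Pa.

    The unit comes from the ``pressure_unit`` column if present, else the
    ``pressure_unit`` argument, else Pa.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"dataset file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DatasetError(f"cannot parse {path}: {exc}") from exc
    missing = {"conc_g_per_L", "pressure"} - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        warnings.warn(f"{path}: header-only file, empty dataset", stacklevel=2)
        return OsmoticDataset(
            np.empty(0), np.empty(0), system=system, provenance=str(path)
        )

    conc = pd.to_numeric(df["conc_g_per_L"], errors="coerce").to_numpy()
    pressure = pd.to_numeric(df["pressure"], errors="coerce").to_numpy(dtype=float)
    for name, col in (("conc_g_per_L", conc), ("pressure", pressure)):
        bad = np.flatnonzero(np.isnan(col)).tolist()
        if bad:
            raise DatasetError(f"{path}: non-numeric {name} at rows {bad}")
    neg = np.flatnonzero(conc < 0).tolist()
    if neg:
        raise DatasetError(f"{path}: negative concentrations at rows {neg}")

    if "pressure_unit" in df.columns:
        units = df["pressure_unit"].astype(str)
        unknown = sorted(set(units) - set(PRESSURE_UNITS))
        if unknown:
            raise DatasetError(f"{path}: unknown pressure units {unknown}")
        factors = units.map(PRESSURE_UNITS).to_numpy(dtype=float)
        pressure = pressure * factors
    elif pressure_unit is not None:
        pressure = convert_pressure(pressure, pressure_unit, "Pa")
    return OsmoticDataset(conc, pressure, system=system, provenance=str(path))


def write_dataset(dataset: OsmoticDataset, path, pressure_unit: str = "Pa") -> None:
    """Write an osmometry dataset as CSV in the requested pressure unit."""
    df = pd.DataFrame(
        {
            "conc_g_per_L": dataset.conc,
            "pressure": convert_pressure(dataset.pressure_Pa, "Pa", pressure_unit),
            "pressure_unit": pressure_unit,
        }
    )
    df.to_csv(path, index=False)


# -- run configuration ---------------------------------------------------


class SpeciesConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    id: str
    role: str
    molar_mass: float = pydantic.Field(gt=0)
    dissociation_count: int = pydantic.Field(default=1, ge=1)

    def to_species(self) -> Species:
        return Species(self.id, self.role, self.molar_mass, self.dissociation_count)


class ConditionsConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    temperature_K: float = pydantic.Field(gt=0)
    V1_m3_per_mol: Optional[float] = pydantic.Field(default=None, gt=0)


class PrepConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    protein_g_per_L: float = pydantic.Field(default=0.0, ge=0)
    salt_M: float = pydantic.Field(default=0.0, ge=0)
    basis_L: float = pydantic.Field(default=1.0, gt=0)
    partial_specific_volume_mL_per_g: float = pydantic.Field(default=0.733, gt=0)
    water_density_g_per_mL: float = pydantic.Field(default=WATER_DENSITY, gt=0)


class BindingConfig(pydantic.BaseModel):
    """Hydration either directly (g/g or mol/mol) or via a SASA in Å²."""

    model_config = pydantic.ConfigDict(extra="forbid")
    hydration_g_per_g: Optional[float] = pydantic.Field(default=None, ge=0)
    hydration_mol_per_mol: Optional[float] = pydantic.Field(default=None, ge=0)
    sasa_A2: Optional[float] = pydantic.Field(default=None, ge=0)
    coverage_per_nm2: float = pydantic.Field(default=15.2, gt=0)
    ion_binding_mol_per_mol: float = pydantic.Field(default=0.0, ge=0)

    @pydantic.model_validator(mode="after")
    def _one_hydration(self):
        given = [
            v
            for v in (self.hydration_g_per_g, self.hydration_mol_per_mol, self.sasa_A2)
            if v is not None
        ]
        if len(given) != 1:
            raise ValueError(
                "binding: give exactly one of hydration_g_per_g, "
                "hydration_mol_per_mol, sasa_A2"
            )
        return self


class RunConfig(pydantic.BaseModel):
    """Full solution description: species, conditions, prep, binding."""

    model_config = pydantic.ConfigDict(extra="forbid")
    species: List[SpeciesConfig]
    conditions: ConditionsConfig
    prep: PrepConfig = PrepConfig()
    binding: Optional[BindingConfig] = None

    @pydantic.model_validator(mode="after")
    def _roles(self):
        roles = [s.role for s in self.species]
        if roles.count("solvent") != 1:
            raise ValueError("species: exactly one solvent required")
        if roles.count("protein") != 1:
            raise ValueError("species: exactly one protein (macromolecule) required")
        if roles.count("salt") > 1:
            raise ValueError("species: at most one salt supported")
        if self.prep.salt_M > 0 and roles.count("salt") == 0:
            raise ValueError("prep.salt_M > 0 but no salt species declared")
        return self

    def _by_role(self, role: str) -> Optional[SpeciesConfig]:
        for s in self.species:
            if s.role == role:
                return s
        return None

    def to_system(self) -> SolutionSystem:
        solvent = self._by_role("solvent")
        protein = self._by_role("protein")
        salt = self._by_role("salt")
        v1 = self.conditions.V1_m3_per_mol
        if v1 is None:
            v1 = solvent.molar_mass / self.prep.water_density_g_per_mL * 1e-6
        return SolutionSystem(
            protein=protein.to_species(),
            conditions=ThermoConditions(
                temperature=self.conditions.temperature_K,
                solvent_partial_molar_volume=v1,
            ),
            salt=salt.to_species() if salt else None,
            salt_molarity=self.prep.salt_M if salt else 0.0,
            partial_specific_volume=self.prep.partial_specific_volume_mL_per_g,
            water_density=self.prep.water_density_g_per_mL,
            water_molar_mass=solvent.molar_mass,
            basis_volume=self.prep.basis_L,
        )

    def binding_parameters(self) -> tuple[float, float]:
        """(hydration mol/mol, ion binding mol/mol) from the binding block."""
        if self.binding is None:
            raise ValidationError("config has no binding block")
        protein = self._by_role("protein")
        solvent = self._by_role("solvent")
        b = self.binding
        if b.hydration_mol_per_mol is not None:
            h = b.hydration_mol_per_mol
        elif b.hydration_g_per_g is not None:
            h = hydration_g_per_g_to_mol_per_mol(
                b.hydration_g_per_g, protein.molar_mass, solvent.molar_mass
            )
        else:
            h = hydration_from_sasa(
                b.sasa_A2,
                b.coverage_per_nm2,
                protein.molar_mass,
                solvent.molar_mass,
            ).molar_hydration
        return h, b.ion_binding_mol_per_mol


def read_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
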