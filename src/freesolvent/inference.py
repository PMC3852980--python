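"""Regression of hydration and ion binding from osmometry datasets.

Thin functional wrapper over :class:`freesolvent.model.FreeSolventModel`:
datasets carry their solution context, so a fit needs only the data, a
choice of free parameters, and optionally a starting point. The point of
the exercise is the robustness check — binding parameters regressed from
pressure data should land on the independently determined (SASA-monolayer,
ion-binding-assay) values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .composition import hydration_from_sasa, hydration_mol_per_mol_to_g_per_g
from .dataset import OsmoticDataset
from .exceptions import ValidationError
from .model import FreeSolventModel

DEFAULT_HYDRATION_BOUNDS = (0.0, 12000.0)
DEFAULT_ION_BINDING_BOUNDS = (0.0, 50.0)


@dataclass
class FitResult:
    """Outcome of a binding-parameter regression."""

    hydration_mol_per_mol: float
    hydration_g_per_g: float
    ion_binding: float
    residuals: np.ndarray  # model - observed, Pa
    rmse: float  # Pa
    stderr: dict  # approximate, free parameters only
    converged: bool
    n_evals: int
    free_parameters: tuple

    def to_dict(self) -> dict:
        return {
            "estimates": {
                "hydration_mol_per_mol": self.hydration_mol_per_mol,
                "hydration_g_per_g": self.hydration_g_per_g,
                "ion_binding_mol_per_mol": self.ion_binding,
            },
            "rmse_Pa": self.rmse,
            "stderr": self.stderr,
            "converged": self.converged,
            "n_evals": self.n_evals,
            "free_parameters": list(self.free_parameters),
            "residuals_Pa": self.residuals.tolist(),
        }


def fit_binding_parameters(
    dataset: OsmoticDataset,
    fit_hydration: bool = True,
    fit_ion_binding: bool = True,
    init: Optional[dict] = None,
    hydration_bounds: tuple = DEFAULT_HYDRATION_BOUNDS,
    ion_binding_bounds: tuple = DEFAULT_ION_BINDING_BOUNDS,
    sasa: Optional[float] = None,
    relative_weighting: bool = False,
) -> FitResult:
    """Regress (ν12, ν32) from an osmometry dataset.

    ``init`` may supply ``hydration`` (mol/mol) and/or ``ion_binding``
    starting values (and values for fixed parameters). When a ``sasa``
    (Å²) is given, the SASA-monolayer hydration seeds the fit; otherwise
    unspecified starting values default to the bound-box midpoints.
    """
    if dataset.system is None:
        raise ValidationError("dataset has no solution context (system=None)")
    if dataset.n_distinct_conc < 2:
        raise ValidationError("fitting requires >= 2 distinct concentrations")
    init = dict(init or {})
    if "hydration" not in init:
        if sasa is not None:
            spec = hydration_from_sasa(
                sasa,
                macromolecule_molar_mass=dataset.system.protein.molar_mass,
                water_molar_mass=dataset.system.water_molar_mass,
            )
            init["hydration"] = spec.molar_hydration
        else:
            init["hydration"] = 0.5 * (hydration_bounds[0] + hydration_bounds[1])
    if "ion_binding" not in init:
        init["ion_binding"] = 0.5 * (ion_binding_bounds[0] + ion_binding_bounds[1])
    for key, (lo, hi) in (
        ("hydration", hydration_bounds),
        ("ion_binding", ion_binding_bounds),
    ):
        if not (lo <= init[key] <= hi):
            raise ValidationError(f"init {key}={init[key]} outside bounds [{lo}, {hi}]")

    sys = dataset.system
    model = FreeSolventModel(
        hydration=init["hydration"],
        ion_binding=init["ion_binding"],
        protein_molar_mass=sys.protein.molar_mass,
        salt_molarity=sys.salt_molarity,
        salt_molar_mass=sys.salt.molar_mass if sys.salt else 58.443,
        salt_dissociation=sys.salt.dissociation_count if sys.salt else 2,
        temperature=sys.conditions.temperature,
        solvent_molar_volume=sys.conditions.solvent_partial_molar_volume,
        partial_specific_volume=sys.partial_specific_volume,
        water_density=sys.water_density,
        water_molar_mass=sys.water_molar_mass,
        fit_hydration=fit_hydration,
        fit_ion_binding=fit_ion_binding,
        hydration_bounds=hydration_bounds,
        ion_binding_bounds=ion_binding_bounds,
        relative_weighting=relative_weighting,
    )
    model.fit(dataset.conc.reshape(-1, 1), dataset.pressure_Pa)
    return FitResult(
        hydration_mol_per_mol=model.hydration_,
        hydration_g_per_g=hydration_mol_per_mol_to_g_per_g(
            model.hydration_, sys.protein.molar_mass, sys.water_molar_mass
        ),
        ion_binding=model.ion_binding_,
        residuals=model.residuals_,
        rmse=model.rmse_,
        stderr=model.stderr_,
        converged=model.converged_,
        n_evals=model.n_evals_,
        free_parameters=model.free_parameters_,
    )
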