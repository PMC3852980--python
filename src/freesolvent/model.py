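"""Scikit-learn-style estimator for the free-solvent osmotic pressure model.

``FreeSolventModel`` is a physical regression model: X is a single column of
macromolecule concentrations (g/L), y the osmotic pressures (Pa). With
hydration and ion binding supplied from independent measurements (SASA
monolayer, Scatchard-type ion binding) it is a pure predictor; ``fit``
regresses whichever of the two parameters are left free against osmometry
data by bounded nonlinear least squares.

The estimator composes with sklearn tooling (``get_params``/``set_params``,
``clone``, pipelines, ``GridSearchCV`` over the physical constants); the
fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .activity import activity_coefficient_from_pressure, predict_activity_coefficient
from .composition import (
    Species,
    SolutionSystem,
    ThermoConditions,
    WATER_DENSITY,
    WATER_MOLAR_MASS,
    hydration_mol_per_mol_to_g_per_g,
)
from .core import osmotic_pressure_freesolvent
from .exceptions import FreeSolventError, ValidationError

#: Residual (Pa) returned for parameter/concentration combinations where the
#: binding is infeasible; large and finite so the optimizer backs away from
#: the saturation boundary instead of crashing on it.
INFEASIBLE_PENALTY = 1.0e8


class FreeSolventModel(RegressorMixin, BaseEstimator):
    """Free-solvent osmotic pressure model for one macromolecule + one salt.

    Parameters
    ----------
    hydration : float
        Water binding ν12, mol H2O per mol macromolecule. The default is the
        SASA-monolayer value for BSA (27,746 Å² × 15.2 waters/nm²).
    ion_binding : float
        Salt binding ν32, mol salt formula units per mol macromolecule.
    protein_molar_mass, salt_molar_mass : float
        g/mol. Salt may be absent (``salt_molarity=0``).
    salt_molarity : float
        Chamber-I (and initial chamber-II) salt concentration, mol/L.
    salt_dissociation : int
        Ions per salt formula unit (2 for NaCl/KCl).
    temperature : float
        K.
    solvent_molar_volume : float or None
        V̄1 in m³/mol; ``None`` derives it from the water density and molar
        mass.
    partial_specific_volume : float
        v̄ of the macromolecule, mL/g, used to account for the water the
        macromolecule excludes from the basis volume.
    fit_hydration, fit_ion_binding : bool
        Which parameters ``fit`` treats as free.
    hydration_bounds, ion_binding_bounds : tuple
        Box constraints for the regression.
    relative_weighting : bool
        If True, minimize relative instead of absolute pressure residuals.

    Attributes
    ----------
    hydration_, ion_binding_ : float
        Regressed (or carried-through fixed) parameters after ``fit``.
    hydration_g_per_g_ : float
        ``hydration_`` re-expressed in g water per g macromolecule.
    residuals_ : ndarray
        Signed residuals (model − observed), Pa, at the solution.
    rmse_ : float
        Root-mean-square residual, Pa.
    stderr_ : dict
        Approximate standard errors from the local quadratic model, for the
        free parameters only.
    converged_ : bool
    n_evals_ : int
    """

    def __init__(
        self,
        hydration: float = 4217.392,
        ion_binding: float = 11.59,
        protein_molar_mass: float = 66430.0,
        salt_molarity: float = 0.15,
        salt_molar_mass: float = 58.443,
        salt_dissociation: int = 2,
        temperature: float = 298.15,
        solvent_molar_volume: Optional[float] = None,
        partial_specific_volume: float = 0.733,
        water_density: float = WATER_DENSITY,
        water_molar_mass: float = WATER_MOLAR_MASS,
        fit_hydration: bool = True,
        fit_ion_binding: bool = True,
        hydration_bounds: tuple = (0.0, 12000.0),
        ion_binding_bounds: tuple = (0.0, 50.0),
        relative_weighting: bool = False,
    ):
        self.hydration = hydration
        self.ion_binding = ion_binding
        self.protein_molar_mass = protein_molar_mass
        self.salt_molarity = salt_molarity
        self.salt_molar_mass = salt_molar_mass
        self.salt_dissociation = salt_dissociation
        self.temperature = temperature
        self.solvent_molar_volume = solvent_molar_volume
        self.partial_specific_volume = partial_specific_volume
        self.water_density = water_density
        self.water_molar_mass = water_molar_mass
        self.fit_hydration = fit_hydration
        self.fit_ion_binding = fit_ion_binding
        self.hydration_bounds = hydration_bounds
        self.ion_binding_bounds = ion_binding_bounds
        self.relative_weighting = relative_weighting

    # -- plumbing ---------------------------------------------------------

    def system(self) -> SolutionSystem:
        """The :class:`SolutionSystem` implied by the constructor parameters."""
        v1 = self.solvent_molar_volume
        if v1 is None:
            v1 = self.water_molar_mass / self.water_density * 1e-6
        cond = ThermoConditions(
            temperature=self.temperature, solvent_partial_molar_volume=v1
        )
        protein = Species("macromolecule", "protein", self.protein_molar_mass, 1)
        salt = None
        if self.salt_molarity > 0:
            salt = Species(
                "salt", "salt", self.salt_molar_mass, self.salt_dissociation
            )
        return SolutionSystem(
            protein=protein,
            conditions=cond,
            salt=salt,
            salt_molarity=self.salt_molarity,
            partial_specific_volume=self.partial_specific_volume,
            water_density=self.water_density,
            water_molar_mass=self.water_molar_mass,
        )

    def _current_params(self) -> tuple[float, float]:
        if hasattr(self, "hydration_"):
            return self.hydration_, self.ion_binding_
        return self.hydration, self.ion_binding

    def _validate_X(self, X) -> np.ndarray:
        X = check_array(X, ensure_2d=True, dtype=float)
        if X.shape[1] != 1:
            raise ValidationError(
                "X must be a single column of concentrations in g/L"
            )
        if np.any(X < 0):
            raise ValidationError("concentrations must be >= 0")
        return X

    def _pressures(
        self, conc: np.ndarray, hydration: float, ion_binding: float
    ) -> np.ndarray:
        """Model pressures in Pa; NaN where binding is infeasible."""
        system = self.system()
        binding = system.binding(hydration, ion_binding)
        comp_i = system.chamber(0.0, "I")
        out = np.empty(conc.shape[0])
        for k, c in enumerate(conc):
            try:
                comp_ii = system.chamber(float(c), "II")
                out[k] = osmotic_pressure_freesolvent(
                    comp_ii, comp_i, binding, system.conditions
                )
            except FreeSolventError:
                out[k] = np.nan
        return out

    # -- sklearn API ------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Osmotic pressure (Pa) at each concentration in ``X`` (g/L).

        Uses the regressed parameters after :meth:`fit`, otherwise the
        constructor values — the model is a full predictor without any
        fitting, its parameters being independently measurable.
        """
        X = self._validate_X(X)
        hydration, ion_binding = self._current_params()
        pi = self._pressures(X[:, 0], hydration, ion_binding)
        if np.any(np.isnan(pi)):
            bad = np.flatnonzero(np.isnan(pi)).tolist()
            raise FreeSolventError(
                f"binding infeasible at rows {bad}: concentration beyond the "
                "hydration-saturation boundary"
            )
        return pi

    def predict_activity(self, X) -> np.ndarray:
        """γ1 of free-solvent at each concentration in ``X`` (g/L)."""
        X = self._validate_X(X)
        hydration, ion_binding = self._current_params()
        system = self.system()
        binding = system.binding(hydration, ion_binding)
        comp_i = system.chamber(0.0, "I")
        out = np.empty(X.shape[0])
        for k, c in enumerate(X[:, 0]):
            comp_ii = system.chamber(float(c), "II")
            out[k] = predict_activity_coefficient(comp_ii, comp_i, binding)
        return out

    def activity_from_pressure(self, X, pi_Pa) -> np.ndarray:
        """Back-calculate γ1 from measured pressures aligned with ``X``."""
        X = self._validate_X(X)
        pi = np.asarray(pi_Pa, dtype=float).ravel()
        if pi.shape[0] != X.shape[0]:
            raise ValidationError("pi_Pa must align with X")
        system = self.system()
        comp_i = system.chamber(0.0, "I")
        out = np.empty(X.shape[0])
        for k, c in enumerate(X[:, 0]):
            comp_ii = system.chamber(float(c), "II")
            out[k] = activity_coefficient_from_pressure(
                float(pi[k]), comp_ii, comp_i, system.conditions
            )
        return out

    def fit(self, X, y):
        """Regress the free binding parameters against osmometry data.

        Bounded nonlinear least squares on the pressure residuals
        (absolute Pa by default, relative if ``relative_weighting``).
        Non-convergence is flagged on ``converged_``, not raised.
        """
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValidationError("X and y must have equal length")
        if not np.all(np.isfinite(y)):
            raise ValidationError("y must be finite")
        conc = X[:, 0]

        free: list[str] = []
        if self.fit_hydration:
            free.append("hydration")
        if self.fit_ion_binding:
            if self.salt_molarity <= 0:
                raise ValidationError(
                    "cannot fit ion_binding in a salt-free system"
                )
            free.append("ion_binding")
        if not free:
            raise ValidationError("no free parameters: nothing to fit")
        if np.unique(conc).shape[0] < len(free):
            raise ValidationError(
                f"{len(free)} free parameter(s) need at least as many distinct "
                f"concentrations; got {np.unique(conc).shape[0]}"
            )

        x0, lo, hi, scale = [], [], [], []
        if "hydration" in free:
            x0.append(float(np.clip(self.hydration, *self.hydration_bounds)))
            lo.append(self.hydration_bounds[0])
            hi.append(self.hydration_bounds[1])
            scale.append(max(1.0, 0.1 * (self.hydration_bounds[1] - self.hydration_bounds[0])))
        if "ion_binding" in free:
            x0.append(float(np.clip(self.ion_binding, *self.ion_binding_bounds)))
            lo.append(self.ion_binding_bounds[0])
            hi.append(self.ion_binding_bounds[1])
            scale.append(max(1.0, 0.1 * (self.ion_binding_bounds[1] - self.ion_binding_bounds[0])))

        def unpack(theta):
            it = iter(theta)
            h = next(it) if "hydration" in free else self.hydration
            nu3 = next(it) if "ion_binding" in free else self.ion_binding
            return h, nu3

        denom = np.where(np.abs(y) > 1.0, np.abs(y), 1.0)

        def residuals(theta):
            h, nu3 = unpack(theta)
            pi = self._pressures(conc, h, nu3)
            r = pi - y
            r[np.isnan(pi)] = INFEASIBLE_PENALTY
            if self.relative_weighting:
                r = r / denom
            return r

        res = least_squares(
            residuals,
            x0=np.asarray(x0),
            bounds=(np.asarray(lo), np.asarray(hi)),
            method="trf",
            x_scale=np.asarray(scale),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )

        h, nu3 = unpack(res.x)
        self.hydration_ = float(h)
        self.ion_binding_ = float(nu3)
        self.hydration_g_per_g_ = hydration_mol_per_mol_to_g_per_g(
            self.hydration_, self.protein_molar_mass, self.water_molar_mass
        )
        r = self._pressures(conc, self.hydration_, self.ion_binding_) - y
        self.residuals_ = r
        self.rmse_ = float(np.sqrt(np.mean(r**2)))
        self.converged_ = bool(res.success)
        self.n_evals_ = int(res.nfev)
        self.free_parameters_ = tuple(free)
        self.stderr_ = self._standard_errors(res, len(conc), len(free))
        self.n_features_in_ = 1
        return self

    def _standard_errors(self, res, n_obs: int, n_free: int) -> dict:
        dof = n_obs - n_free
        if dof <= 0 or res.jac is None:
            return {p: math.nan for p in self.free_parameters_}
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * (2.0 * res.cost / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            return {p: math.nan for p in self.free_parameters_}
        return dict(zip(self.free_parameters_, se.tolist()))

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "hydration_")


def _check_fitted(model: FreeSolventModel) -> None:
    check_is_fitted(model)
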