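"""Activity coefficient of free-solvent: prediction and back-calculation.

The headline quantity. Equating the non-ideal osmotic law written in the
*total* water mole fraction with the free-solvent law written in the *free*
water mole fraction gives a closed form for the activity coefficient of
free-solvent in the protein chamber,

    γ1_II = (x̂1_II / x1_II) · (x1_I / x̂1_I),

which, because the protein-free chamber is ideal (x̂1_I = x1_I, γ1_I = 1),
reduces to the ratio x̂1_II / x1_II. Every input is an independently
measurable physical quantity — composition, hydration, ion binding — with
no adjustable parameters. The inverse route recovers γ1 from a measured
osmotic pressure:

    γ1_II = (x1_I / x1_II) · exp(-π V̄1 / (R T)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .composition import (
    BindingMatrix,
    ChamberComposition,
    SolutionSystem,
    ThermoConditions,
)
from .core import free_water_mole_fraction, total_water_mole_fraction
from .exceptions import FreeSolventError, ValidationError

#: The protein-free chamber is an ideal dilute-electrolyte solution by
#: construction; its free-solvent activity coefficient is identically 1.
GAMMA_CHAMBER_I = 1.0


def predict_activity_coefficient(
    comp_II: ChamberComposition,
    comp_I: ChamberComposition,
    binding: BindingMatrix,
) -> float:
    """γ1 of free-solvent in chamber II from hydration and ion binding."""
    x_hat_ii = free_water_mole_fraction(comp_II, binding)
    x_ii = total_water_mole_fraction(comp_II)
    x_hat_i = free_water_mole_fraction(comp_I, binding)
    x_i = total_water_mole_fraction(comp_I)
    gamma = (x_hat_ii / x_ii) * (x_i / x_hat_i)
    if gamma > 1.0 + 1e-12:
        warnings.warn(
            f"activity coefficient {gamma:.6g} exceeds 1; the supplied "
            "hydration/ion-binding combination is physically unusual",
            stacklevel=2,
        )
    return gamma


def activity_coefficient_from_pressure(
    pi: float,
    comp_II: ChamberComposition,
    comp_I: ChamberComposition,
    cond: ThermoConditions,
) -> float:
    """γ1 of free-solvent back-calculated from an osmotic pressure in Pa."""
    if not math.isfinite(pi):
        raise ValidationError("osmotic pressure must be finite")
    x_ii = total_water_mole_fraction(comp_II)
    x_i = total_water_mole_fraction(comp_I)
    return (x_i / x_ii) * math.exp(-pi / cond.rt_over_v1)


@dataclass
class ActivityCurve:
    """γ1 of free-solvent per macromolecule concentration.

    ``errors`` holds (row index, exception) pairs for rows that could not be
    evaluated (e.g. infeasible binding at very high concentration); the
    corresponding gamma entries are NaN.
    """

    conc: np.ndarray  # g/L
    gamma: np.ndarray
    mode: str  # "predicted" or "calculated"
    errors: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"conc_g_per_L": self.conc, "gamma": self.gamma, "mode": self.mode}
        )

    def __len__(self) -> int:
        return len(self.conc)


def activity_curve(
    system: SolutionSystem,
    conc: Sequence[float],
    hydration_mol_per_mol: float,
    ion_binding: float = 0.0,
    mode: str = "predicted",
    pressures_Pa: Optional[Sequence[float]] = None,
) -> ActivityCurve:
    """Vectorize γ1 over a concentration grid.

    ``mode="predicted"`` uses the physical-parameter closed form;
    ``mode="calculated"`` inverts measured pressures (``pressures_Pa``,
    aligned with ``conc``). Rows that fail are recorded in ``errors`` with
    their indices rather than silently dropped.
    """
    if mode not in ("predicted", "calculated"):
        raise ValidationError("mode must be 'predicted' or 'calculated'")
    conc = np.asarray(conc, dtype=float)
    if mode == "calculated":
        if pressures_Pa is None:
            raise ValidationError("mode='calculated' requires pressures_Pa")
        pressures = np.asarray(pressures_Pa, dtype=float)
        if pressures.shape != conc.shape:
            raise ValidationError("pressures_Pa must align with conc")
    binding = system.binding(hydration_mol_per_mol, ion_binding)
    comp_i = system.chamber(0.0, "I")
    gamma = np.full(conc.shape, np.nan)
    errors: list = []
    for k, c in enumerate(conc):
        try:
            comp_ii = system.chamber(float(c), "II")
            if mode == "predicted":
                gamma[k] = predict_activity_coefficient(comp_ii, comp_i, binding)
            else:
                gamma[k] = activity_coefficient_from_pressure(
                    float(pressures[k]), comp_ii, comp_i, system.conditions
                )
        except FreeSolventError as exc:  # noqa: PERF203 - per-row reporting
            errors.append((k, exc))
    return ActivityCurve(conc=conc, gamma=gamma, mode=mode, errors=errors)
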