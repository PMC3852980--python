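"""Osmometry dataset container: (concentration, pressure) observations."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .composition import SolutionSystem
from .exceptions import DatasetError


class OsmoticDataset:
    """A series of membrane-osmometry observations.

    ``conc`` in g/L, ``pressure_Pa`` in Pa; ``system`` carries the solution
    context (species, chamber-I salt, conditions) needed to evaluate the
    model against the data. ``provenance`` is a free-form tag (a citation,
    a simulation seed, a file path).
    """

    def __init__(
        self,
        conc,
        pressure_Pa,
        system: Optional[SolutionSystem] = None,
        provenance: str = "",
    ):
        self.conc = np.asarray(conc, dtype=float)
        self.pressure_Pa = np.asarray(pressure_Pa, dtype=float)
        self.system = system
        self.provenance = provenance
        if self.conc.ndim != 1 or self.pressure_Pa.ndim != 1:
            raise DatasetError("conc and pressure must be 1-D")
        if self.conc.shape != self.pressure_Pa.shape:
            raise DatasetError("conc and pressure must have equal length")
        if np.any(self.conc < 0):
            bad = np.flatnonzero(self.conc < 0).tolist()
            raise DatasetError(f"negative concentrations at rows {bad}")
        if not np.all(np.isfinite(self.pressure_Pa)):
            bad = np.flatnonzero(~np.isfinite(self.pressure_Pa)).tolist()
            raise DatasetError(f"non-finite pressures at rows {bad}")

    def __len__(self) -> int:
        return int(self.conc.shape[0])

    def __repr__(self) -> str:
        tag = f", provenance={self.provenance!r}" if self.provenance else ""
        return f"OsmoticDataset(n={len(self)}{tag})"

    @property
    def n_distinct_conc(self) -> int:
        return int(np.unique(self.conc).shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "conc_g_per_L": self.conc,
                "pressure": self.pressure_Pa,
                "pressure_unit": "Pa",
            }
        )
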