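"""Exception hierarchy for the free-solvent model."""


class FreeSolventError(Exception):
    """Base class for all package errors."""


class ValidationError(FreeSolventError, ValueError):
    """Invalid species, composition or parameter values."""


class InfeasibleCompositionError(FreeSolventError):
    """A preparation recipe that cannot physically exist on the basis volume
    (e.g. the macromolecule's excluded volume exceeds the basis volume)."""


class InfeasibleBindingError(FreeSolventError):
    """Bound moles of a diffusible species exceed the moles available.

    Physically this marks the model's saturation boundary: the hydration
    shell would require more water (or salt) than the solution contains.
    """

    def __init__(self, species_id: str, bound: float, available: float):
        self.species_id = species_id
        self.bound = bound
        self.available = available
        super().__init__(
            f"binding infeasible for species {species_id!r}: "
            f"{bound:.6g} mol bound exceeds {available:.6g} mol available"
        )


class DatasetError(FreeSolventError, ValueError):
    """Malformed osmometry dataset (missing columns, bad units, bad rows)."""
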