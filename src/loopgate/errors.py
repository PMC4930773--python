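"""Exception hierarchy shared across the package."""


class LoopgateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LoopgateError):
    """A coordinate file could not be parsed."""


class TopologyError(LoopgateError):
    """Frames of an ensemble do not share the same residue topology."""


class SelectionError(LoopgateError):
    """A selection expression is malformed or refers to missing entities."""


class MissingAtomError(LoopgateError):
    """A required atom (e.g. a C-alpha) is absent from a residue."""


class MutationError(LoopgateError):
    """A point mutation cannot be applied to the template structure."""


class ConfigurationError(LoopgateError):
    """A required parameter, table entry or input is missing or inconsistent."""


class FitError(LoopgateError):
    """A nonlinear fit failed to converge or produced inadmissible parameters."""


class DetectionError(LoopgateError):
    """A signal feature (peak, transition midpoint) could not be located."""


class AnalysisError(LoopgateError):
    """A structural analysis precondition is violated (pairing, degeneracy...)."""
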