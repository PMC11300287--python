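"""Exception hierarchy shared across the pipeline."""


class CSHError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CSHError, ValueError):
    """A file does not have the expected structure (dimensionality, dtype)."""


class ValidationError(CSHError, ValueError):
    """Structurally readable input violates a domain invariant."""


class CalibrationError(CSHError):
    """Median scaling is undefined (e.g. zero target median)."""


class DegenerateLesionError(CSHError):
    """A lesion has no valid voxels; its hypoxia fraction is undefined."""


class InfeasibleMatchError(CSHError):
    """1:1 matching cannot keep every reference patient (target too small)."""
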