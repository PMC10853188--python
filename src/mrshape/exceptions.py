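"""Exception hierarchy shared across the package."""


class MRShapeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MRShapeError):
    """Invalid configuration or unusable input schema."""


class OrientationError(MRShapeError):
    """Minor-allele orientation is impossible (e.g. missing allele frequency)."""


class AlignmentError(MRShapeError):
    """Exposure and outcome allele sets cannot be reconciled."""


class PalindromeAmbiguityError(AlignmentError):
    """Palindromic pair whose allele frequencies are too close to 0.5 to resolve strand."""


class LDLookupError(MRShapeError):
    """A required SNP is absent from the LD matrix."""


class InsufficientInstrumentsError(MRShapeError):
    """Too few usable SNPs for the requested estimator."""


class CalibrationError(MRShapeError):
    """Degenerate design in allometric-coefficient calibration."""


class DomainError(MRShapeError):
    """Argument outside the mathematical domain of an operation."""
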