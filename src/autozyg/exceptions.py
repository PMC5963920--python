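"""Exception types raised across the package."""


class AutozygError(Exception):
    """Base class for all package errors."""


class FormatError(AutozygError):
    """A text input file violates its dialect (bad column count, symbol, ...)."""


class PedigreeError(AutozygError):
    """A pedigree violates its structural invariants."""


class ConfigurationError(AutozygError):
    """A configuration is inconsistent or unusable for the requested analysis."""


class ReferenceMismatchError(AutozygError):
    """A stated reference base disagrees with the coding sequence."""


class IncompleteSegregationData(AutozygError):
    """Segregation cannot be evaluated because a family member lacks a genotype.

    Deliberately distinct from a ``False`` segregation result: an untyped
    member is missing evidence, not counter-evidence.
    """


class SimulationError(AutozygError):
    """A simulation could not satisfy its construction constraints."""
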