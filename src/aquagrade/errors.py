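"""Exception hierarchy.

``InputDataError`` maps to CLI exit code 2, ``ConfigurationError`` to 3.
"""


class AquagradeError(Exception):
    """Base class for all package errors."""


class InputDataError(AquagradeError):
    """Malformed or physically impossible user input (bad CSV cell, negative
    concentration, incomplete sample)."""


class IncompleteSampleError(InputDataError):
    """A well sample is missing an indicator required by the requested stage."""


class ConfigurationError(AquagradeError):
    """Invalid configuration: unknown scheme/indicator, degenerate standard,
    infeasible generator settings."""


class DegenerateSampleError(InputDataError):
    """All-zero cations or anions: no Piper point can be computed."""


class InsufficientDataError(InputDataError):
    """Too few samples for the requested statistic."""


class UnplantableScenarioError(ConfigurationError):
    """A planted-grade scenario targets a zero-width class interval."""
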