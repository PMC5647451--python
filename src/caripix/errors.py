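"""Exception hierarchy.

``CaripixError`` is the base class; ``InputError`` marks problems with user
inputs (files, configs, degenerate data) and maps to CLI exit code 1, while
anything else maps to exit code 2.
"""


class CaripixError(Exception):
    """Base class for all package errors."""


class InputError(CaripixError):
    """Malformed or degenerate user input (file, config, data)."""


class NoFiducialError(CaripixError):
    """No usable Cu-fiducial signal in a line scan."""


class InsufficientOverlapError(CaripixError):
    """Registered scans share too little depth range for analysis."""


class DegenerateDesignError(InputError):
    """Calibration references do not span distinct concentrations."""


class NoLesionError(CaripixError):
    """Profile shows no demineralized lesion (informational, rarely raised)."""


class UndefinedCorrelationError(CaripixError):
    """Correlation requested on constant input."""
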