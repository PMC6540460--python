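"""Exception hierarchy.

Validation problems (bad configs, malformed files, wrong shapes) raise
subclasses of :class:`ValidationError`; numerical failures during training
raise :class:`DivergenceError`.  The CLI maps the former to exit code 2 and
the latter to exit code 3.
"""


class OscilloBPError(Exception):
    """Base class for all package errors."""


class ValidationError(OscilloBPError, ValueError):
    """Invalid user input: bad argument, malformed file, bad shape."""


class ConfigurationError(ValidationError):
    """A configuration field is out of its valid range."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class DegenerateSampleError(ValidationError):
    """A sample with zero variance where spread is required."""


class ShapeError(ValidationError):
    """Array dimensions do not match the model or operation."""


class DivergenceError(OscilloBPError, ArithmeticError):
    """Training produced non-finite parameters or loss."""
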