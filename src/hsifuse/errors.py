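"""Exception hierarchy for the hsifuse toolkit."""


class HsiError(Exception):
    """Base class for all hsifuse errors."""


class DimensionError(HsiError, ValueError):
    """Array axes or shapes do not match what an operation requires."""


class ValidationError(HsiError, ValueError):
    """Input values violate an operation's preconditions (non-finite,
    non-positive reference, constant image where contrast is required, ...)."""


class FormatError(HsiError, IOError):
    """A container file does not conform to the expected layout; the message
    names the missing dataset or attribute."""


class ParameterError(HsiError, ValueError):
    """A user-supplied parameter is out of its admissible range."""


class SelectionError(HsiError, RuntimeError):
    """Band selection could not reach the requested subset size."""


class RegistrationError(HsiError, RuntimeError):
    """Keypoint-based registration failed (too few inlier matches)."""


class AlignmentError(HsiError, RuntimeError):
    """Iterative intensity-based alignment diverged."""


class MetricError(HsiError, ValueError):
    """A validation metric is undefined for the given inputs."""


class ConfigError(HsiError, ValueError):
    """A workflow definition failed validation before execution."""
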