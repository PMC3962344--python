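"""Exception hierarchy with stable CLI exit codes.

Every error class carries the process exit code the command-line tool uses
when the error propagates out of a subcommand.  Codes: 2 input, 3 config,
4 registration, 5 layout, 6 pipeline, 7 analysis, 8 scoring.
"""


class LarvatrackError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(LarvatrackError):
    """Unreadable paths, malformed values, or inputs violating a precondition."""

    exit_code = 2


class FormatError(InputError):
    """Readable input with inconsistent or unsupported structure (e.g. mixed frame sizes)."""


class EmptyRecordingError(InputError):
    """A recording that yields fewer than two sampled frames (nothing to difference)."""


class ConfigError(LarvatrackError):
    """Invalid run configuration or assay design."""

    exit_code = 3


class RegistrationError(LarvatrackError):
    """Alignment-dot detection or transform estimation failed."""

    exit_code = 4


class LayoutError(LarvatrackError):
    """Dish layout invalid or dish region outside the imaged frame."""

    exit_code = 5


class PipelineError(LarvatrackError):
    """Inconsistent intermediate data while assembling tracking results."""

    exit_code = 6


class AnalysisError(LarvatrackError):
    """Invalid statistical input (e.g. zero stimulus-only mean, Bliss fraction outside [0,1])."""

    exit_code = 7


class ScoringError(LarvatrackError):
    """Tracker output and ground truth do not describe the same scene."""

    exit_code = 8
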