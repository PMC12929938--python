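"""Exception hierarchy; CLI exit codes hang off these classes."""


class PoredelayError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(PoredelayError):
    """Invalid or inconsistent configuration values."""

    exit_code = 2


class DataError(PoredelayError):
    """Malformed, degenerate or insufficient input data."""

    exit_code = 3


class DegenerateTraceError(DataError):
    """A trace that cannot be processed (constant, too short, all-zero)."""


class IndeterminateEventError(DataError):
    """An event too short to produce any spectrogram frame in the decision region."""


class TrainingError(PoredelayError):
    """Model training or curve fitting failed to converge."""

    exit_code = 4


class FitError(TrainingError):
    """Nonlinear least-squares fit did not converge; carries diagnostics."""
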