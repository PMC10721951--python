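"""Exception hierarchy for tjkit.

All tjkit errors derive from :class:`TJKitError` so callers can catch the
package's failures with one clause while still distinguishing configuration
mistakes from data problems and numerical failures.
"""


class TJKitError(Exception):
    """Base class for all tjkit errors."""


class ConfigurationError(TJKitError, ValueError):
    """An invalid configuration value (names the offending field)."""


class DataError(TJKitError, ValueError):
    """Malformed or physically impossible input data."""


class FitError(TJKitError, RuntimeError):
    """Nonlinear fit failed to converge or produced a degenerate solution."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ThresholdError(TJKitError, RuntimeError):
    """No expression cutoff satisfies the requested density-ratio property."""


class MeasurementError(TJKitError, ValueError):
    """A physically inconsistent measurement (e.g. current with zero voltage)."""


class OutOfRangeError(TJKitError, ValueError):
    """A potential outside the physically attainable (Nernst-bounded) range."""
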