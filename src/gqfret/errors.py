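"""Exception hierarchy for gqfret."""


class GqFretError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GqFretError):
    """Unknown preset / variant name or inconsistent configuration."""


class ValidationError(GqFretError):
    """Domain object violates one of its invariants."""


class IntegrationError(GqFretError):
    """ODE solver failed; carries the failing segment."""

    def __init__(self, message: str, segment=None):
        super().__init__(message)
        self.segment = segment


class DataError(GqFretError):
    """Malformed trace data (e.g. non-positive donor sample)."""

    def __init__(self, message: str, index=None):
        super().__init__(message)
        self.index = index


class NormalizationError(GqFretError):
    """Degenerate trace: baseline and plateau windows coincide."""


class FitError(GqFretError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class CalibrationError(GqFretError):
    """Refined rate calibration did not reach its tolerance."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals
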