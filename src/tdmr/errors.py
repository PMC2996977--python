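"""Exception hierarchy.

All package errors derive from :class:`TdmrError` so the CLI can map any
validation failure to exit code 2.
"""


class TdmrError(Exception):
    """Base class for all tdmr errors."""


class ConfigError(TdmrError):
    """Invalid or unknown configuration."""


class ValidationError(TdmrError):
    """Malformed input data or inconsistent arguments."""


class SizingError(TdmrError):
    """A simulated chromosome is too small for the requested layout."""


class ParameterError(TdmrError):
    """A simulation parameter is infeasible (e.g. implied probability > 1)."""


class CalibrationError(TdmrError):
    """Threshold calibration failed for a tissue comparison."""


class MeasurementError(TdmrError):
    """An undefined or missing wet-lab measurement."""


class PipelineError(TdmrError):
    """A pipeline stage aborted; the message names the stage."""
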