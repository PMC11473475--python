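"""Exception and warning types shared across the pipeline."""


class CEMQAError(Exception):
    """Base class for all cemqa errors."""


class GeometryError(CEMQAError):
    """Phantom/frame geometry is inconsistent (plug outside field of view, overlapping patches, ...)."""


class ProfileError(CEMQAError):
    """A system profile violates its physical constraints (non-positive means, negative noise, ...)."""


class MeasurementError(CEMQAError):
    """An ROI/ring cannot be measured (clipped by the image border, too few pixels, ...)."""


class DegenerateNoiseError(CEMQAError):
    """CNR requested with zero background noise; the ratio is undefined, never infinity."""


class ExposureParseError(CEMQAError):
    """A mandatory exposure tag is missing or malformed; the message names the tag."""


class FactorRangeError(CEMQAError):
    """HVL/thickness query falls outside the dose-factor grid by more than one grid step."""


class PairingError(CEMQAError):
    """Reference and comparator CNR tables do not share the required keys."""


class ConfigurationError(CEMQAError):
    """Inconsistent study configuration (mismatched phantom specs across systems, ...)."""


class InsufficientDataError(CEMQAError):
    """Fewer data points than an operation's minimum (e.g. < 3 iodine densities for a line fit)."""


class LocalizationWarning(UserWarning):
    """Plug-center refinement failed or hit its search window; the nominal center was used."""


class CalibrationWarning(UserWarning):
    """A calibration target is not exactly attainable; residuals are reported instead of failing."""
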