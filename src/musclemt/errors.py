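"""Exception hierarchy for the musclemt pipeline."""


class MuscleMTError(Exception):
    """Base class for all musclemt errors."""


class ConfigurationError(MuscleMTError, ValueError):
    """A configuration object violates one of its invariants."""


class InputError(MuscleMTError, ValueError):
    """An operation received input outside its stated domain."""


class GeometryError(MuscleMTError, ValueError):
    """Detected line geometry is incompatible with thickness measurement
    (e.g. a near-vertical line where a quasi-horizontal aponeurosis was
    expected)."""


class DetectionFailureError(MuscleMTError, RuntimeError):
    """The pipeline could not find the two aponeurosis lines."""


class NoLineError(DetectionFailureError):
    """The Hough accumulator is empty: no line can be extracted."""


class DegenerateDataError(MuscleMTError, ValueError):
    """Agreement statistics were requested on data with no variance."""
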